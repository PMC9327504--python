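scanner,slide,slide_class,scan_time_s,size_mm2,printed_norm_time
A,1,resection,66,479.4,31
A,2,resection,87,695.7,28.1
A,3,resection,67,490.7,30.7
A,4,biopsy,33,157.9,47
A,5,biopsy,42,266.5,35.5
A,6,biopsy,15,67.7,49.9
A,7,ihc,120,768,35.2
A,8,ihc,108,625.2,38.9
A,9,ihc,11,41.4,59.8
B,1,resection,257,692.1,83.6
B,2,resection,272,677.1,90.4
B,3,resection,195,457.7,95.9
B,4,biopsy,94,156.8,134.9
B,5,biopsy,126,353.9,80.1
B,6,biopsy,76,81.3,210.4
B,7,ihc,184,377.5,109.7
B,8,ihc,150,486,69.4
B,9,ihc,37,34.6,240.6
C,1,resection,541,537.1,226.6
C,2,resection,778,777,225.3
C,3,resection,528,571.7,207.8
C,4,biopsy,250,184.8,304.4
C,5,biopsy,384,425.2,203.2
C,6,biopsy,92,84,246.4
C,7,ihc,810,897.7,203
C,8,ihc,681,803.2,190.8
C,9,ihc,81,57.7,315.6
D,1,resection,1022,506.2,454.2
D,2,resection,1150,448.8,576.6
D,3,resection,905,439.6,463.2
D,4,biopsy,302,111.7,608.2
D,5,biopsy,417,100,938
D,6,biopsy,186,67.2,622.4
D,7,ihc,959,290.9,741.7
D,8,ihc,775,199.2,875.4
D,9,ihc,207,36.7,1268.9
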