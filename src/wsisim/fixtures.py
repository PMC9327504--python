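"""Embedded benchmark fixture: four scanners timed on nine slides.

The fixture reproduces a published benchmark of four commercial whole-slide
scanners (labelled A-D) on a shared set of nine slides — three H&E-stained
resections, three H&E-stained biopsies, and three IHC slides spanning
34.6-897.7 mm^2 of scanned area.  Each cell holds the measured scan time,
the scanned area, and the normalized time as printed in the source table
(scan time / area x 225 mm^2, rounded to one decimal).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_table1", "TABLE1_CAPACITIES"]

#: Per-batch slide capacity of the four benchmarked scanners.
TABLE1_CAPACITIES: dict[str, int] = {"A": 360, "B": 6, "C": 210, "D": 100}


def load_table1() -> pd.DataFrame:
    """Load the embedded 9-slide x 4-scanner benchmark.

    Returns a long-format DataFrame with columns ``scanner``, ``slide``,
    ``slide_class``, ``scan_time_s``, ``size_mm2`` and ``printed_norm_time``
    (36 rows).
    """
    with resources.files("wsisim.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    df["slide"] = df["slide"].astype(int)
    return df
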