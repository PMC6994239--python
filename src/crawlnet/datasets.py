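"""Loaders for the small reference tables packaged with crawlnet.

Two tables from the larval locomotor literature ship as CSV fixtures:

* ``coactive_groups.csv`` -- membership of the 30 body-wall muscles in the
  four forward (F1-F4) and four backward (B1-B4) co-activated muscle groups.
* ``pmn_mn_adjacency.csv`` -- binary premotor->motor adjacency by neuron
  name, with each motor neuron's spatial muscle group.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# Muscles whose recruitment order flips between behaviors: 15-17 move early in
# backward crawling; 2, 11 and 18 move late.
DIFFERENTIAL_EARLY_BACKWARD = (15, 16, 17)
DIFFERENTIAL_LATE_BACKWARD = (2, 11, 18)


def _read(name: str) -> pd.DataFrame:
    with resources.files("crawlnet.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def coactive_groups() -> pd.DataFrame:
    """Long table with columns ``direction``, ``group``, ``muscle``."""
    return _read("coactive_groups.csv")


def coactive_group_map(direction: str) -> dict[int, str]:
    """Muscle number -> CMUG label (F1..F4 or B1..B4) for one direction."""
    df = coactive_groups()
    sub = df.loc[df["direction"] == direction]
    if len(sub) == 0:
        raise KeyError(f"unknown direction {direction!r}")
    return dict(zip(sub["muscle"].astype(int), sub["group"]))


def pmn_mn_adjacency() -> pd.DataFrame:
    """Long table with columns ``mn``, ``muscle_group``, ``pmn``."""
    return _read("pmn_mn_adjacency.csv")
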