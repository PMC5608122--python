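"""Published summary tables of the emulated gated/ungated carotid study.

Two small CSVs ship with the package: the distribution table (median [IQR]
per metric, sequence and weighting, from repeat 1) and the repeatability
table (Bland-Altman bias and 95% LOA range per metric and sequence).  They
provide worked-example inputs for the normalized-LOA-percentage computation
(LOA range / distribution median x 100) and fixtures for acceptance checks.

The study's published normalized percentage for the T2W gated wall SNR
(33.3%) does not follow from its published median (10.0) and LOA range (3.0),
which give 30.0%; it was presumably computed from unrounded internal values.
``normalized_loa_table`` therefore reports what the printed inputs imply and
makes no claim about that figure.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import normalized_loa_pct

__all__ = ["reference_distributions", "reference_repeatability", "normalized_loa_table"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("vesselrep.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def reference_distributions() -> pd.DataFrame:
    """Published distribution medians and IQRs (repeat 1)."""
    return _load("reference_distributions.csv")


def reference_repeatability() -> pd.DataFrame:
    """Published Bland-Altman bias and 95% LOA range per metric and arm."""
    return _load("reference_repeatability.csv")


def normalized_loa_table() -> pd.DataFrame:
    """Normalized LOA percentages from the published tables.

    Joins the repeatability LOA ranges with the distribution medians and adds
    ``loa_pct = loa_range / median * 100`` for every intensity and area
    metric present in both tables.
    """
    dist = reference_distributions()[["weighting", "metric", "sequence", "median"]]
    rep = reference_repeatability()
    merged = rep.merge(dist, on=["weighting", "metric", "sequence"], validate="one_to_one")
    merged["loa_pct"] = [
        normalized_loa_pct(r, m) for r, m in zip(merged["loa_range"], merged["median"])
    ]
    return merged
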