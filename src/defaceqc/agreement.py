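"""Inter-rater agreement: percent agreement and Cohen's kappa.

Used to quantify how consistently two raters label defacing success, per
defacing method and criterion.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

__all__ = ["AgreementReport", "rater_agreement", "agreement_table"]


@dataclasses.dataclass
class AgreementReport:
    """Raw percent agreement and chance-corrected kappa for one label pair."""

    percent_agreement: float
    kappa: float
    n: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def rater_agreement(labels_a, labels_b) -> AgreementReport:
    """Percent agreement and Cohen's kappa between two raters.

    kappa = (p_o - p_e) / (1 - p_e) with the expected agreement p_e from
    the product of the raters' marginal label frequencies. When chance
    agreement is total (p_e = 1, both raters constant on the same label),
    kappa is defined as 1 if the observed agreement is also total and 0
    otherwise, with a warning.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1D and of equal length")
    n = len(a)
    if n == 0:
        raise ValueError("empty label vectors")

    p_o = float(np.mean(a == b))
    cats = np.unique(np.concatenate([a, b]))
    p_e = float(
        sum(np.mean(a == c) * np.mean(b == c) for c in cats)
    )
    if p_e >= 1.0 - 1e-15:
        if p_o < 1.0:
            warnings.warn(
                "total chance agreement (both raters constant); kappa "
                "defined as 0"
            )
            kappa = 0.0
        else:
            kappa = 1.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementReport(
        percent_agreement=100.0 * p_o, kappa=float(kappa), n=n
    )


def agreement_table(
    labels: pd.DataFrame,
    rater_a: str = "rater_a",
    rater_b: str = "rater_b",
    by: tuple = ("method", "criterion"),
) -> pd.DataFrame:
    """Agreement per defacing method and criterion.

    ``labels`` holds one row per rated scan with the two raters' labels and
    the grouping columns.
    """
    rows = []
    for keys, grp in labels.groupby(list(by)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        rep = rater_agreement(grp[rater_a].to_numpy(),
                              grp[rater_b].to_numpy())
        rows.append({**dict(zip(by, keys)), **rep.as_dict()})
    return pd.DataFrame(rows)
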