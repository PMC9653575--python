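"""Method-agreement statistics for paired MTV/SUVmax measurements.

Two measurement methods (e.g. an automated pipeline and a reference) are
compared with Pearson correlation, the two-way single-measurement
absolute-agreement intraclass correlation (ICC(2,1)) with its F-based 95%
confidence interval, Bland-Altman bias and limits of agreement, RMSE with
signed biases, and per-method coefficients of variation. Sample (n-1)
standard deviations are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "AgreementSummary",
    "pearson",
    "icc_agreement",
    "bland_altman",
    "rmse_and_bias",
    "coefficient_of_variation",
    "cv_percent",
    "summarize_agreement",
]


@dataclass
class PairedMeasurements:
    """Aligned measurements of the same subjects by two methods."""

    subject_ids: np.ndarray
    method_a: np.ndarray
    method_b: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.method_a = np.asarray(self.method_a, dtype=np.float64)
        self.method_b = np.asarray(self.method_b, dtype=np.float64)
        if not (len(self.subject_ids) == len(self.method_a) == len(self.method_b)):
            raise ValueError("subject ids and both measurement vectors must align")
        if not (np.isfinite(self.method_a).all() and np.isfinite(self.method_b).all()):
            raise ValueError("measurements must be finite")

    def __len__(self) -> int:
        return len(self.method_a)

    @classmethod
    def from_arrays(cls, a, b, ids=None) -> "PairedMeasurements":
        a = np.asarray(a, dtype=np.float64)
        if ids is None:
            ids = np.arange(len(a))
        return cls(np.asarray(ids), a, np.asarray(b, dtype=np.float64))

    @property
    def differences(self) -> np.ndarray:
        """Paired differences A - B."""
        return self.method_a - self.method_b


@dataclass
class AgreementSummary:
    n: int
    pearson_r: float
    pearson_p: float
    icc: float
    icc_ci95: tuple[float, float]
    icc_p: float
    mean_diff: float
    loa_low: float
    loa_high: float
    rmse: float
    positive_bias: float
    negative_bias: float
    mean_a: float
    sd_a: float
    cv_a: float
    mean_b: float
    sd_b: float
    cv_b: float

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["icc_ci95"] = list(self.icc_ci95)
        return d


def pearson(pairs: PairedMeasurements) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value."""
    if len(pairs) < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    if np.std(pairs.method_a) == 0 or np.std(pairs.method_b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(pairs.method_a, pairs.method_b)
    return float(r), float(p)


def icc_agreement(pairs: PairedMeasurements, variant: str = "ICC2"
                  ) -> tuple[float, float, float, float]:
    """Intraclass correlation between the two methods.

    The default ``ICC2`` is the two-way random-effects, single-measurement,
    absolute-agreement coefficient (the usual choice for method
    comparison); other pingouin variants ("ICC1", "ICC3") can be selected.
    Returns (icc, ci_low, ci_high, p).
    """
    import pingouin as pg

    if len(pairs) < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if np.std(pairs.method_a) == 0 and np.std(pairs.method_b) == 0 \
            and np.std(pairs.differences) == 0:
        raise ValueError("ICC undefined for fully degenerate data")
    n = len(pairs)
    df = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "rater": np.repeat(["A", "B"], n),
        "score": np.concatenate([pairs.method_a, pairs.method_b]),
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        table = pg.intraclass_corr(df, targets="subject", raters="rater",
                                   ratings="score", nan_policy="raise")
    # pingouin labels rows either Shrout-Fleiss style ("ICC2") or
    # McGraw-Wong style ("ICC(A,1)") depending on version
    aliases = {"ICC1": ("ICC1", "ICC(1,1)"), "ICC2": ("ICC2", "ICC(A,1)"),
               "ICC3": ("ICC3", "ICC(C,1)")}
    wanted = aliases.get(variant, (variant,))
    row = table[table["Type"].isin(wanted)].iloc[0]
    ci = row["CI95%"] if "CI95%" in table.columns else row["CI95"]
    icc, lo, hi = float(row["ICC"]), float(ci[0]), float(ci[1])
    pval = float(row["pval"])
    if not np.isfinite(lo) or not np.isfinite(hi):
        # perfect agreement: the F statistics degenerate and the CI collapses
        lo, hi = icc, icc
        pval = 0.0 if np.isnan(pval) else pval
    return icc, lo, hi, pval


def bland_altman(pairs: PairedMeasurements) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement (mean +- 1.96 SD)."""
    if len(pairs) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = pairs.differences
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def rmse_and_bias(pairs: PairedMeasurements) -> tuple[float, float, float]:
    """RMSE of the paired differences plus signed bias components.

    With d = reference (A) - method (B): RMSE = sqrt(mean d^2); the
    positive bias is the mean of the positive differences (0 if none) and
    the negative bias the mean magnitude of the negative ones (0 if none).
    """
    if len(pairs) < 1:
        raise ValueError("need at least one pair")
    d = pairs.differences
    rmse = float(np.sqrt(np.mean(d ** 2)))
    pos = d[d > 0]
    neg = d[d < 0]
    pos_bias = float(pos.mean()) if pos.size else 0.0
    neg_bias = float(np.abs(neg).mean()) if neg.size else 0.0
    return rmse, pos_bias, neg_bias


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, 100*SD/mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean


def coefficient_of_variation(values) -> tuple[float, float, float]:
    """(mean, sample SD, CV%) of a measurement vector."""
    v = np.asarray(values, dtype=np.float64)
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return mean, sd, cv_percent(mean, sd)


def summarize_agreement(pairs: PairedMeasurements, icc_variant: str = "ICC2"
                        ) -> AgreementSummary:
    """All agreement statistics for one paired comparison."""
    r, p = pearson(pairs)
    icc, lo, hi, icc_p = icc_agreement(pairs, variant=icc_variant)
    mean_diff, loa_low, loa_high = bland_altman(pairs)
    rmse, pos, neg = rmse_and_bias(pairs)
    mean_a, sd_a, cv_a = coefficient_of_variation(pairs.method_a)
    mean_b, sd_b, cv_b = coefficient_of_variation(pairs.method_b)
    return AgreementSummary(
        n=len(pairs), pearson_r=r, pearson_p=p,
        icc=icc, icc_ci95=(lo, hi), icc_p=icc_p,
        mean_diff=mean_diff, loa_low=loa_low, loa_high=loa_high,
        rmse=rmse, positive_bias=pos, negative_bias=neg,
        mean_a=mean_a, sd_a=sd_a, cv_a=cv_a,
        mean_b=mean_b, sd_b=sd_b, cv_b=cv_b,
    )


def bland_altman_figure(pairs: PairedMeasurements, title: str = "", ax=None):
    """Bland-Altman plot (matplotlib Axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mean_diff, lo, hi = bland_altman(pairs)
    means = (pairs.method_a + pairs.method_b) / 2.0
    ax.scatter(means, pairs.differences, s=14, alpha=0.7)
    for y, style in ((mean_diff, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (A - B)")
    if title:
        ax.set_title(title)
    return ax
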