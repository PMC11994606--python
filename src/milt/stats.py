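"""Tumor proportion score (TPS) arithmetic and agreement statistics.

The TPS of a slide is the percentage of viable tumor cells showing any
partial or complete membranous PD-L1 staining; a slide is scorable only
when at least 100 viable tumor cells are present.  Model-vs-reference
agreement is quantified the way method-comparison studies do it:
ICC(2,1) for the continuous scores, Cohen's kappa at the clinical 1% and
50% cutoffs, Bland–Altman limits of agreement, and one-vs-rest rates on
the three expression subgroups (<1%, 1–49%, >=50%).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import scipy.stats
from sklearn.metrics import cohen_kappa_score, confusion_matrix

MIN_VIABLE_TUMOR_CELLS = 100

#: Expression subgroups in increasing order of PD-L1 positivity.
TPS_BINS = ("no_expression", "low_expression", "high_expression")

#: Kappa interpretation bands: (upper bound, label); upper bound inclusive.
KAPPA_BANDS = (
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "almost perfect"),
)


class InvalidSlideError(ValueError):
    """Raised when a slide has too few viable tumor cells to be scored."""

    def __init__(self, n_viable: int):
        self.n_viable = n_viable
        super().__init__(
            f"TPS requires >= {MIN_VIABLE_TUMOR_CELLS} viable tumor cells, "
            f"got {n_viable}"
        )


@dataclass(frozen=True)
class CellCounts:
    """Positive and viable tumor-cell counts on one slide."""

    n_positive_tumor_cells: int
    n_viable_tumor_cells: int

    def __post_init__(self):
        if not 0 <= self.n_positive_tumor_cells <= self.n_viable_tumor_cells:
            raise ValueError(
                "need 0 <= n_positive <= n_viable, got "
                f"{self.n_positive_tumor_cells}/{self.n_viable_tumor_cells}"
            )


def compute_tps(counts: CellCounts) -> float:
    """TPS percent = 100 * positive tumor cells / viable tumor cells.

    Raises :class:`InvalidSlideError` below the 100-cell validity minimum.
    """
    if counts.n_viable_tumor_cells < MIN_VIABLE_TUMOR_CELLS:
        raise InvalidSlideError(counts.n_viable_tumor_cells)
    return 100.0 * counts.n_positive_tumor_cells / counts.n_viable_tumor_cells


def bin_tps(tps: float) -> str:
    """Map a TPS percent to its expression subgroup.

    <1% -> no expression, 1–49% -> low, >=50% -> high.  The 49–50%
    boundary is resolved as high iff TPS >= 50, consistent with the
    clinical 50% cutoff used for the kappa analysis.
    """
    if not 0.0 <= tps <= 100.0:
        raise ValueError(f"TPS percent out of range [0, 100]: {tps}")
    if tps < 1.0:
        return TPS_BINS[0]
    if tps < 50.0:
        return TPS_BINS[1]
    return TPS_BINS[2]


def percent_to_fraction(tps_percent: float) -> float:
    return tps_percent / 100.0


def fraction_to_percent(tps_fraction: float) -> float:
    return tps_fraction * 100.0


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

def icc(
    pairs: Sequence[tuple[float, float]], alpha: float = 0.05
) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares (subjects x raters, one
    observation per cell) with the McGraw & Wong F-based confidence
    interval.  This is the standard form for method-vs-reference
    agreement: a constant offset between the two columns lowers it,
    unlike the consistency form ICC(3,1).

    Parameters
    ----------
    pairs
        ``(truth, prediction)`` tuples, n >= 5.
    alpha
        Two-sided CI level (default 95% CI).

    Returns
    -------
    (icc, ci_low, ci_high)
    """
    data = np.asarray(pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) table")
    n = data.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 pairs for ICC, got {n}")
    k = 2

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)

    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    if ss_total < 1e-12:
        warnings.warn("zero total variance: ICC degenerate, reported as 1.0")
        return 1.0, 1.0, 1.0

    msr = ss_rows / (n - 1)        # between-subjects
    msc = ss_cols / (k - 1)        # between-raters
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-15:
        warnings.warn("degenerate ANOVA decomposition: ICC reported as 1.0")
        return 1.0, 1.0, 1.0
    icc_val = (msr - mse) / denom

    # McGraw & Wong (1996) CI for ICC(A,1), Satterthwaite df.
    a = k * icc_val / (n * (1.0 - icc_val)) if icc_val < 1.0 else np.inf
    b = 1.0 + k * icc_val * (n - 1.0) / (n * (1.0 - icc_val)) if icc_val < 1.0 else np.inf
    if not np.isfinite(a) or mse == 0.0:
        return icc_val, icc_val, icc_val
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den
    f_low = scipy.stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = scipy.stats.f.ppf(1 - alpha / 2, v, n - 1)
    ci_low = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ci_high = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return float(icc_val), float(ci_low), float(ci_high)


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

def kappa_band(kappa: float) -> str:
    """Interpretation band of a kappa value (0–0.2 slight ... 0.8–1 almost perfect)."""
    for upper, label in KAPPA_BANDS:
        if kappa <= upper:
            return label
    return KAPPA_BANDS[-1][1]


def cohens_kappa(
    truth: Sequence, prediction: Sequence
) -> tuple[float, str]:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Expected agreement p_e uses the marginal products.  When both raters
    are constant and identical (p_e = 1) the statistic is undefined and
    is reported as 1.0 with a warning.
    """
    truth = np.asarray(truth)
    prediction = np.asarray(prediction)
    if truth.shape != prediction.shape:
        raise ValueError("truth and prediction must have equal length")
    if truth.size == 0:
        raise ValueError("empty input")
    labels = np.unique(np.concatenate([truth, prediction]))
    if labels.size == 1:
        warnings.warn("both raters constant and equal: kappa reported as 1.0")
        return 1.0, kappa_band(1.0)
    k = float(cohen_kappa_score(truth, prediction, labels=labels))
    return k, kappa_band(k)


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

def bland_altman(pairs: Sequence[tuple[float, float]]) -> dict:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 SD).

    Differences are prediction - truth in TPS points; SD is the sample
    (ddof=1) standard deviation.
    """
    data = np.asarray(pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 3:
        raise ValueError("need an (n>=3, 2) table of (truth, prediction)")
    d = data[:, 1] - data[:, 0]
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "mean_diff": mean_diff,
        "loa_low": mean_diff - 1.96 * sd,
        "loa_high": mean_diff + 1.96 * sd,
    }


# ---------------------------------------------------------------------------
# Subgroup confusion matrix
# ---------------------------------------------------------------------------

def tps_confusion(truth_bins: Sequence[str], pred_bins: Sequence[str]) -> dict:
    """3x3 confusion matrix over expression subgroups plus one-vs-rest rates.

    Rows are truth, columns prediction, both ordered no/low/high.  For
    each subgroup, accuracy, precision, recall (sensitivity) and
    specificity are computed one-vs-rest; rates with an empty denominator
    are reported as NaN.
    """
    truth_bins = list(truth_bins)
    pred_bins = list(pred_bins)
    if len(truth_bins) == 0:
        raise ValueError("empty input")
    if len(truth_bins) != len(pred_bins):
        raise ValueError("length mismatch")
    for b in truth_bins + pred_bins:
        if b not in TPS_BINS:
            raise ValueError(f"unknown bin label {b!r}")
    mat = confusion_matrix(truth_bins, pred_bins, labels=list(TPS_BINS))
    total = mat.sum()
    rates = {}
    for i, label in enumerate(TPS_BINS):
        tp = mat[i, i]
        fn = mat[i, :].sum() - tp
        fp = mat[:, i].sum() - tp
        tn = total - tp - fn - fp
        rates[label] = {
            "accuracy": (tp + tn) / total,
            "precision": tp / (tp + fp) if tp + fp > 0 else float("nan"),
            "recall": tp / (tp + fn) if tp + fn > 0 else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp > 0 else float("nan"),
        }
    return {"matrix": mat, "labels": list(TPS_BINS), "rates": rates}


# ---------------------------------------------------------------------------
# Pearson chi-square on contingency tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    counts: tuple
    row_labels: tuple = ()
    col_labels: tuple = ()

    def as_array(self) -> np.ndarray:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValueError("negative counts")
        if arr.sum() <= 0:
            raise ValueError("empty table")
        return arr


def chi_square(table: ContingencyTable | Sequence) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    Returns (X^2, degrees of freedom, p-value).  Expected counts come
    from the row/column marginals; a zero marginal makes the expected
    count undefined and raises.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(tuple(map(tuple, table)))
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero row or column marginal")
    x2, p, df, _ = scipy.stats.chi2_contingency(arr, correction=False)
    return float(x2), int(df), float(p)


# ---------------------------------------------------------------------------
# Aggregate agreement report
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Full agreement suite between predicted and reference TPS (percent)."""

    n: int
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    kappa_at_1pct: float
    kappa_at_1pct_band: str
    kappa_at_50pct: float
    kappa_at_50pct_band: str
    bland_altman: dict
    confusion: dict = field(repr=False)

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["confusion"] = {
            "matrix": np.asarray(self.confusion["matrix"]).tolist(),
            "labels": self.confusion["labels"],
            "rates": self.confusion["rates"],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def agreement_report(
    truth_percent: Sequence[float], pred_percent: Sequence[float]
) -> AgreementReport:
    """Compute the full agreement suite for paired TPS percents."""
    truth = np.asarray(truth_percent, dtype=float)
    pred = np.asarray(pred_percent, dtype=float)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError("truth and prediction must be equal-length vectors")
    pairs = list(zip(truth, pred))
    icc_val, lo, hi = icc(pairs)
    k1, b1 = cohens_kappa(truth >= 1.0, pred >= 1.0)
    k50, b50 = cohens_kappa(truth >= 50.0, pred >= 50.0)
    ba = bland_altman(pairs)
    conf = tps_confusion([bin_tps(t) for t in truth], [bin_tps(p) for p in pred])
    return AgreementReport(
        n=len(pairs),
        icc=icc_val,
        icc_ci_low=lo,
        icc_ci_high=hi,
        kappa_at_1pct=k1,
        kappa_at_1pct_band=b1,
        kappa_at_50pct=k50,
        kappa_at_50pct_band=b50,
        bland_altman=ba,
        confusion=conf,
    )


def agreement_plots(truth_percent, pred_percent, out_prefix) -> list:
    """Write scatter (with ICC annotation) and Bland–Altman PNGs.

    Returns the list of file paths written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    truth = np.asarray(truth_percent, dtype=float)
    pred = np.asarray(pred_percent, dtype=float)
    icc_val, lo, hi = icc(list(zip(truth, pred)))
    paths = []

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(truth, pred, s=18, alpha=0.8, edgecolor="none")
    ax.plot([0, 100], [0, 100], "k--", lw=0.8)
    ax.set_xlabel("TPS-Truth (%)")
    ax.set_ylabel("TPS-AI (%)")
    ax.set_title(f"ICC = {icc_val:.3f} (95% CI {lo:.3f}–{hi:.3f})")
    p = f"{out_prefix}_scatter.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    ba = bland_altman(list(zip(truth, pred)))
    d = pred - truth
    m = (pred + truth) / 2
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(m, d, s=18, alpha=0.8, edgecolor="none")
    for y, style in [(ba["mean_diff"], "-"), (ba["loa_low"], "--"), (ba["loa_high"], "--")]:
        ax.axhline(y, color="r", ls=style, lw=0.8)
    ax.set_xlabel("Mean of methods (%)")
    ax.set_ylabel("TPS-AI − TPS-Truth (%)")
    p = f"{out_prefix}_bland_altman.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
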