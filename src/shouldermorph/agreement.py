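"""Blinded-evaluation statistics for a panel of categorical raters.

Implements the chance-corrected inter-rater agreement (Fleiss' kappa), the
per-case base-2 vote entropy, per-rater summary statistics from true
positive / false negative counts of the two implant classes, a
logistic-regression "virtual consensus" over the raters' binary votes, and
the exact McNemar test for paired classifier comparison.

A transcription of the published ten-surgeon implant-selection count table
ships with the package (``rater_counts_table()``): per rater, the number of
anatomical and reverse cases correctly identified (TP) and missed (FN) over
a cohort of 50 anatomical and 50 reverse shoulders.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "RatingsMatrix",
    "AgreementStats",
    "EntropyResult",
    "RaterRecord",
    "UndefinedKappaError",
    "fleiss_kappa",
    "case_entropy",
    "panel_entropies",
    "rater_summary",
    "rater_counts_table",
    "load_rater_records",
    "virtual_consensus",
    "mcnemar_test",
    "ratings_to_matrix",
]


class UndefinedKappaError(ValueError):
    """Raised when expected chance agreement is 1 (a single category ever used)."""


@dataclass
class RatingsMatrix:
    """Item x category count table: ``counts[i, j]`` raters put item i in
    category j; every row sums to the panel size k."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (items x categories)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        row_sums = self.counts.sum(axis=1)
        if self.counts.shape[0] < 1 or not np.all(row_sums == row_sums[0]):
            raise ValueError("every item must be rated by the same number of raters")
        if row_sums[0] < 2:
            raise ValueError("need at least 2 raters per item")

    @property
    def n_items(self) -> int:
        return self.counts.shape[0]

    @property
    def n_raters(self) -> int:
        return int(self.counts.sum(axis=1)[0])

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]


def ratings_to_matrix(ratings: pd.DataFrame | np.ndarray,
                      categories: int | None = None) -> RatingsMatrix:
    """Items x raters categorical table -> items x categories count table.

    Accepts the panel CSV layout (a ``case_id`` column plus one column per
    rater) or a bare array.
    """
    if isinstance(ratings, pd.DataFrame):
        cols = [c for c in ratings.columns if c != "case_id"]
        arr = ratings[cols].to_numpy()
    else:
        arr = np.asarray(ratings)
    if categories is None:
        categories = int(arr.max()) + 1
    counts = np.stack([np.bincount(row.astype(int), minlength=categories) for row in arr])
    return RatingsMatrix(counts)


@dataclass
class AgreementStats:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    per_item_agreement: np.ndarray
    category_proportions: np.ndarray


def fleiss_kappa(m: RatingsMatrix | np.ndarray) -> AgreementStats:
    """Fleiss' kappa: ``(Po - Pe) / (1 - Pe)`` with per-item observed
    agreement ``Po_i = sum_j n_ij (n_ij - 1) / (k (k - 1))`` and chance
    agreement ``Pe = sum_j Pj^2`` from the marginal category proportions."""
    if not isinstance(m, RatingsMatrix):
        m = RatingsMatrix(m)
    n = m.counts
    k = m.n_raters
    po_i = (n * (n - 1)).sum(axis=1) / (k * (k - 1))
    po = float(po_i.mean())
    pj = n.sum(axis=0) / (m.n_items * k)
    pe = float((pj**2).sum())
    if pe >= 1.0 - 1e-12:
        raise UndefinedKappaError(
            "kappa undefined: all raters used a single category for every item (Pe = 1)"
        )
    kappa = (po - pe) / (1.0 - pe)
    return AgreementStats(kappa=float(kappa), observed_agreement=po,
                          expected_agreement=pe, per_item_agreement=po_i,
                          category_proportions=pj)


@dataclass
class EntropyResult:
    H: float
    p1: float
    p2: float
    n1: int
    n2: int


def case_entropy(n1: int, n2: int) -> EntropyResult:
    """Base-2 entropy of a two-way vote split; 0 = full agreement, 1 = even
    split. Uses the convention ``0 * log 0 = 0``."""
    n1, n2 = int(n1), int(n2)
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be nonnegative")
    total = n1 + n2
    if total == 0:
        raise ValueError("at least one rater required")
    p1, p2 = n1 / total, n2 / total
    h = 0.0
    for p in (p1, p2):
        if p > 0:
            h -= p * np.log2(p)
    return EntropyResult(H=float(h), p1=p1, p2=p2, n1=n1, n2=n2)


def panel_entropies(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-case vote entropy of a binary rater panel table."""
    cols = [c for c in panel.columns if c != "case_id"]
    arr = panel[cols].to_numpy()
    rows = []
    for i, votes in enumerate(arr):
        n1 = int((votes == 1).sum())
        n2 = int((votes == 0).sum())
        res = case_entropy(n1, n2)
        case = panel["case_id"].iloc[i] if "case_id" in panel else i
        rows.append({"case_id": case, "n_anatomical": n1, "n_reverse": n2,
                     "entropy_bits": res.H})
    return pd.DataFrame(rows)


@dataclass
class RaterRecord:
    """Per-rater counts: anatomical/reverse true positives and false negatives."""

    rater_id: str
    role: str
    a_tp: int
    r_tp: int
    a_fn: int
    r_fn: int

    def __post_init__(self):
        for f in ("a_tp", "r_tp", "a_fn", "r_fn"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")
        if self.a_tp + self.a_fn == 0 or self.r_tp + self.r_fn == 0:
            raise ValueError("each implant class needs at least one case")


def rater_counts_table() -> pd.DataFrame:
    """The packaged ten-surgeon implant-selection count table."""
    with resources.files("shouldermorph.data").joinpath(
            "surgeon_implant_counts.csv").open() as fh:
        return pd.read_csv(fh, dtype={"rater_id": str})


def load_rater_records(source: pd.DataFrame | str | None = None) -> list[RaterRecord]:
    if source is None:
        df = rater_counts_table()
    elif isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, dtype={"rater_id": str})
    return [RaterRecord(str(r.rater_id), str(r.role), int(r.a_tp), int(r.r_tp),
                        int(r.a_fn), int(r.r_fn)) for r in df.itertuples()]


def rater_summary(records: list[RaterRecord]) -> pd.DataFrame:
    """Per-rater accuracy and class sensitivities plus cohort mean / sample SD.

    Sensitivities are ``TP / (TP + FN)`` per class; accuracy is total TP over
    all rated cases. The two summary rows use the sample (n-1) standard
    deviation.
    """
    if not records:
        raise ValueError("need at least one rater record")
    rows = []
    for r in records:
        a_total, r_total = r.a_tp + r.a_fn, r.r_tp + r.r_fn
        rows.append({
            "rater_id": r.rater_id, "role": r.role,
            "accuracy": (r.a_tp + r.r_tp) / (a_total + r_total),
            "a_se": r.a_tp / a_total,
            "r_se": r.r_tp / r_total,
            "a_tp": r.a_tp, "r_tp": r.r_tp, "a_fn": r.a_fn, "r_fn": r.r_fn,
        })
    df = pd.DataFrame(rows)
    num_cols = ["accuracy", "a_se", "r_se", "a_tp", "r_tp", "a_fn", "r_fn"]
    mean_row = {"rater_id": "mean", "role": ""}
    sd_row = {"rater_id": "SD", "role": ""}
    for c in num_cols:
        mean_row[c] = float(df[c].mean())
        sd_row[c] = float(df[c].std(ddof=1))
    return pd.concat([df, pd.DataFrame([mean_row, sd_row])], ignore_index=True)


def virtual_consensus(rater_predictions, true_labels, folds: int = 5,
                      seed: int = 0) -> float:
    """Stratified k-fold cross-validated accuracy of a logistic regression
    on the raters' binary votes — an aggregate "virtual consensus" reader."""
    X = np.asarray(rater_predictions, dtype=float)
    y = np.asarray(true_labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("rater_predictions must be (n_cases, n_raters) matching labels")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in the labels")
    if X.shape[0] < 2 * folds:
        raise ValueError(f"need at least {2 * folds} cases for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        clf = LogisticRegression(max_iter=1000)
        clf.fit(X[tr], y[tr])
        correct += int((clf.predict(X[te]) == y[te]).sum())
    return correct / X.shape[0]


def mcnemar_test(correct_a, correct_b) -> tuple[float, float]:
    """Exact (binomial) two-sided McNemar test on per-case correctness.

    Returns (statistic = min discordant count, p-value).
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("need two equal-length 1-D boolean vectors")
    n01 = int((~a & b).sum())
    n10 = int((a & ~b).sum())
    table = [[int((a & b).sum()), n10], [n01, int((~a & ~b).sum())]]
    res = _sm_mcnemar(table, exact=True)
    return float(min(n01, n10)), float(res.pvalue)
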