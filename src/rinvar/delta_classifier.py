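"""Δ-centrality statistics, the |ΔB_ct| cutoff classifier and ROC calibration.

For each variant the per-site change of every centrality metric is the
mutant-node value minus the wild-type-node value at the mutated position
(Δvalue = mutant value − WT value); B_ct and C_ct differences are quoted
×100.  A variant is called pathogenic-like when the magnitude of its
betweenness shift exceeds a cutoff (0.26 on the ×100 scale by default,
strict inequality), benign-like otherwise.

The cutoff is calibrated by ROC analysis over |ΔB_ct| scores with
gain-of-function variants as positives: AUC is the tie-corrected rank
statistic (equivalently the trapezoid area), the operating point maximizes
the Youden index, and the 95% CI on the AUC comes from DeLong's method.

The module also ships the published reference set of 83 NaV1.7 variants
(30 gain-of-function from painful-syndrome cohorts, 53 presumed-benign
controls) with their reported ΔB_ct values, checksum-guarded.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import CentralityProfile

__all__ = [
    "DeltaRecord",
    "RocResult",
    "DEFAULT_CUTOFF",
    "PATHOGENIC_LIKE",
    "BENIGN_LIKE",
    "compute_delta",
    "classify",
    "group_test",
    "roc",
    "confusion_counts",
    "load_reported_deltas",
    "records_to_frame",
]

DEFAULT_CUTOFF = 0.26
PATHOGENIC_LIKE = "pathogenic-like"
BENIGN_LIKE = "benign-like"

GROUPS = ("GF", "CONTROL")
SUBGROUPS = ("IEM", "SFN", "PEPD", "nABN", "hSNP")

_REPORTED_SHA256 = "93ae3a3a07698606d8639185d5e9554742a50161bb152dc3e9e005e749e60b47"


@dataclass
class DeltaRecord:
    """One variant's mutant-minus-WT centrality differences at the mutated site."""

    label: str
    group: str
    delta_b_ct: float  # ×100 scale
    subgroup: str = ""
    delta_d: float | None = None
    delta_cc_ct: float | None = None
    delta_c_ct: float | None = None  # ×100 scale
    delta_e_ct: float | None = None
    region: str = ""
    call: str = ""

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not np.isfinite(self.delta_b_ct):
            raise ValueError(f"{self.label}: delta_b_ct must be finite")
        if not self.call:
            self.call = classify(self, DEFAULT_CUTOFF)

    @property
    def score(self) -> float:
        return abs(self.delta_b_ct)


def compute_delta(
    wt: CentralityProfile,
    mut: CentralityProfile,
    site,
    label: str = "",
    group: str = "GF",
    subgroup: str = "",
) -> DeltaRecord:
    """Per-site Δ of every metric between a mutant and a WT profile.

    ``site`` is the residue key of the mutated position; it must be a node of
    both graphs (the residue type differs, the position is identical).
    """
    for prof, which in ((wt, "WT"), (mut, "mutant")):
        if site not in prof.b_ct:
            raise KeyError(f"site {site} missing from the {which} profile")
    scale = wt.report_scale
    return DeltaRecord(
        label=label or str(site),
        group=group,
        subgroup=subgroup,
        delta_b_ct=(mut.b_ct[site] - wt.b_ct[site]) * scale,
        delta_d=mut.degree[site] - wt.degree[site],
        delta_cc_ct=mut.cc_ct[site] - wt.cc_ct[site],
        delta_c_ct=(mut.c_ct[site] - wt.c_ct[site]) * scale,
        delta_e_ct=mut.e_ct[site] - wt.e_ct[site],
    )


def classify(rec: DeltaRecord, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Call a variant from its betweenness shift: pathogenic-like iff |ΔB_ct| > cutoff.

    Strict inequality: a score exactly at the cutoff is benign-like.
    Updates ``rec.call`` and returns it.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    call = PATHOGENIC_LIKE if abs(rec.delta_b_ct) > cutoff else BENIGN_LIKE
    rec.call = call
    return call


def group_test(
    gf_values,
    ctrl_values,
    variant: str = "rank-sum",
) -> tuple[float, float]:
    """Two-sided rank-based comparison of |ΔB_ct| between two variant groups.

    The default is the unpaired two-sample rank-sum (Mann-Whitney) test, the
    appropriate form for unpaired groups of unequal size.  ``variant=
    "signed-rank"`` runs the paired Wilcoxon signed-rank form instead (a
    fidelity audit option; it requires equal-length paired samples).

    Returns ``(statistic, p_value)``.
    """
    gf = np.abs(np.asarray(list(gf_values), dtype=float))
    ctrl = np.abs(np.asarray(list(ctrl_values), dtype=float))
    if len(gf) < 2 or len(ctrl) < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant == "rank-sum":
        res = stats.mannwhitneyu(gf, ctrl, alternative="two-sided")
    elif variant == "signed-rank":
        if len(gf) != len(ctrl):
            raise ValueError("signed-rank form requires paired samples of equal length")
        res = stats.wilcoxon(gf, ctrl, alternative="two-sided")
    else:
        raise ValueError(f"unknown test variant {variant!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass
class RocResult:
    """ROC sweep of the |ΔB_ct| score with gain-of-function as positives."""

    thresholds: np.ndarray  # sorted unique scores used as strict-> cutoffs
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci_95: tuple[float, float]
    best_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    counts: dict[str, int] = field(default_factory=dict)  # tp/fp/tn/fn at best_cutoff


def confusion_counts(records: list[DeltaRecord], cutoff: float = DEFAULT_CUTOFF) -> dict[str, int]:
    """tp/fp/tn/fn of the strict |ΔB_ct| > cutoff rule (positives = GF)."""
    tp = sum(1 for r in records if r.group == "GF" and r.score > cutoff)
    fn = sum(1 for r in records if r.group == "GF" and r.score <= cutoff)
    fp = sum(1 for r in records if r.group == "CONTROL" and r.score > cutoff)
    tn = sum(1 for r in records if r.group == "CONTROL" and r.score <= cutoff)
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn}


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    # tie-corrected Mann-Whitney AUC: ties get half credit
    all_scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_scores)
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float, level: float = 0.95):
    """DeLong variance of the AUC via placement values, Wald interval."""
    m, n = len(pos), len(neg)
    # V10[i]: placement of positive i among negatives; V01[j]: of negative j
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def roc(records: list[DeltaRecord]) -> RocResult:
    """Threshold sweep, AUC with DeLong 95% CI, and Youden-optimal cutoff.

    Candidate operating points are the unique |ΔB_ct| scores applied with the
    strict ``score > cutoff`` rule.  The Youden index (sensitivity +
    specificity − 1) picks the best one, ties broken toward the smaller
    cutoff; the reported cutoff is the midpoint between the achieving score
    and the next larger one, i.e. the centre of the indifference interval.
    """
    pos = np.array([r.score for r in records if r.group == "GF"], dtype=float)
    neg = np.array([r.score for r in records if r.group == "CONTROL"], dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC needs both classes present")

    thresholds = np.unique(np.concatenate([pos, neg]))
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])

    auc = _rank_auc(pos, neg)
    ci = _delong_ci(pos, neg, auc)

    youden = sens + spec - 1.0
    best_idx = int(np.argmax(youden))  # argmax takes the first (smallest) on ties
    t = thresholds[best_idx]
    larger = thresholds[thresholds > t]
    best_cutoff = float((t + larger[0]) / 2.0) if len(larger) else float(t)

    counts = {
        "tp": int((pos > best_cutoff).sum()),
        "fn": int((pos <= best_cutoff).sum()),
        "fp": int((neg > best_cutoff).sum()),
        "tn": int((neg <= best_cutoff).sum()),
    }
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci_95=ci,
        best_cutoff=best_cutoff,
        sens_at_cutoff=float(sens[best_idx]),
        spec_at_cutoff=float(spec[best_idx]),
        counts=counts,
    )


class DataIntegrityError(RuntimeError):
    """Packaged reference data does not match its recorded checksum."""


def load_reported_deltas(path: str | Path | None = None) -> list[DeltaRecord]:
    """Load the packaged reference set of 83 variants with reported ΔB_ct values.

    30 gain-of-function records (IEM, SFN and PEPD cohorts) and 53 controls
    (4 nABN, 49 hSNP).  The packaged file is verified against a recorded
    SHA-256 checksum; a user-supplied ``path`` skips the check.
    """
    if path is None:
        raw = resources.files("rinvar.data").joinpath("reported_deltas.tsv").read_bytes()
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _REPORTED_SHA256:
            raise DataIntegrityError(
                f"reported_deltas.tsv checksum mismatch: {digest} != {_REPORTED_SHA256}"
            )
        from io import BytesIO

        df = pd.read_csv(BytesIO(raw), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    records = [
        DeltaRecord(
            label=row.label,
            group=row.group,
            subgroup=row.subgroup,
            region=getattr(row, "region", ""),
            delta_b_ct=float(row.delta_b_ct),
        )
        for row in df.itertuples()
    ]
    return records


def records_to_frame(records: list[DeltaRecord]) -> pd.DataFrame:
    """Flatten records to a DataFrame (for reports and delimited export)."""
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "group": r.group,
                "subgroup": r.subgroup,
                "region": r.region,
                "delta_b_ct": r.delta_b_ct,
                "abs_delta_b_ct": r.score,
                "delta_d": r.delta_d,
                "delta_cc_ct": r.delta_cc_ct,
                "delta_c_ct": r.delta_c_ct,
                "delta_e_ct": r.delta_e_ct,
                "call": r.call,
            }
            for r in records
        ]
    )
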