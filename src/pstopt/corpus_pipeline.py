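"""Re-interpretation of a corpus of two-arm trial results under fixed and flexible thresholds.

The corpus is a delimited table with one row per randomized trial: the
primary effect ``b``, its standard error ``se``, the outcome type
(continuous or dichotomous) and the per-arm sample sizes.  The test
statistic is ``b/se`` for continuous outcomes and ``log(b)/se`` for
dichotomous ones (ratio effects), referred to a Student's t distribution
with ``n1 + n2 - 2`` degrees of freedom — a t rather than a z reference
because some trials are small.

Each surviving trial is classified as significant or not under four
criteria: the fixed thresholds 0.05 and 0.005, the per-trial optimal
threshold (``pst_opt``), and its constrained variant (``c_pst_opt``).
Flexible thresholds are computed from the trial's arm sizes and an assumed
minimum acceptable effect size (0.5 for total n >= 100, otherwise 0.8),
under the equal-variance rescaling — per-trial standard deviations are not
available in effect/SE corpora.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .error_model import StudyDesign, type1_error
from .threshold_optimizer import ConstraintSpec, optimize_constrained, optimize_threshold

__all__ = [
    "ColumnMap",
    "CRITERIA",
    "load_corpus",
    "filter_corpus",
    "assumed_effect_size",
    "classify_corpus",
    "cohen_kappa",
    "summarize_corpus",
]

logger = logging.getLogger(__name__)

CRITERIA = ("fixed_0.05", "fixed_0.005", "pst_opt", "c_pst_opt")
FLEXIBLE_CRITERIA = ("pst_opt", "c_pst_opt")

#: sentinel written wherever a constrained threshold does not exist
NA_SENTINEL = "NA"

#: trials with |statistic| at or above this are excluded (data-entry and
#: unit artefacts produce absurd statistics)
MAX_ABS_STAT = 20.0
#: minimum sample size for inclusion
MIN_SAMPLE = 10


@dataclass(frozen=True)
class ColumnMap:
    """Maps corpus column names onto the fields the pipeline needs.

    ``outcome_labels`` translates the file's outcome-type values onto
    ``{"continuous", "dichotomous"}``; values already equal to those
    (case-insensitively) need no entry.
    """

    effect: str = "b"
    se: str = "se"
    outcome_type: str = "outcome_type"
    n1: str = "n1"
    n2: str = "n2"
    trial_id: str | None = "trial_id"
    outcome_labels: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "ColumnMap":
        """Read a key=value text file (one mapping per line, '#' comments)."""
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                kv[key.strip()] = value.strip()
        labels = {k[len("label."):]: v for k, v in kv.items() if k.startswith("label.")}
        known = {f.name for f in fields(cls)} - {"outcome_labels"}
        unknown = set(kv) - known - {k for k in kv if k.startswith("label.")}
        if unknown:
            raise ValueError(f"unknown column-map keys: {sorted(unknown)}")
        init = {k: v for k, v in kv.items() if k in known}
        return cls(**init, outcome_labels=labels)


def assumed_effect_size(n1: int, n2: int) -> float:
    """Assumed minimum acceptable effect size from the total sample size.

    Trials with total n >= 100 are assumed to target a medium effect
    (d = 0.5); smaller trials are only ethical when targeting a large
    effect, so d = 0.8 is assumed.
    """
    return 0.5 if n1 + n2 >= 100 else 0.8


def _normalize_outcome(value, labels: dict) -> str | None:
    s = str(value).strip()
    s = labels.get(s, s).lower()
    return s if s in ("continuous", "dichotomous") else None


def load_corpus(path, colmap: ColumnMap = ColumnMap(), *, sep: str | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a delimited per-trial table into derived records plus a rejects report.

    Returns ``(records, rejects)``.  ``records`` carries trial_id, b, se,
    outcome_type, n1, n2 and the derived stat, nu, p and d_assumed columns.
    Rows that cannot yield a valid statistic are returned in ``rejects``
    with a machine-readable ``reason`` — counted and reported, never
    silently dropped.
    """
    if sep is None:
        import csv

        with open(path) as fh:
            first = fh.readline()
        try:
            sep = csv.Sniffer().sniff(first, delimiters=",\t;|").delimiter
        except csv.Error:
            sep = ","
    # round_trip: reported effects/SEs must survive write -> read exactly
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    needed = [colmap.effect, colmap.se, colmap.outcome_type, colmap.n1, colmap.n2]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ValueError(f"corpus is missing mapped columns: {missing}")

    if colmap.trial_id is not None and colmap.trial_id in raw.columns:
        ids = raw[colmap.trial_id].astype(str)
    else:
        ids = pd.Series(np.arange(len(raw)).astype(str), index=raw.index)

    records, rejects = [], []

    def reject(tid, reason):
        rejects.append({"trial_id": tid, "reason": reason})

    for idx, row in raw.iterrows():
        tid = ids.loc[idx]
        outcome = _normalize_outcome(row[colmap.outcome_type], colmap.outcome_labels)
        if outcome is None:
            reject(tid, "unknown outcome type")
            continue
        cells = [row[colmap.effect], row[colmap.se], row[colmap.n1], row[colmap.n2]]
        if any(pd.isna(v) for v in cells):
            reject(tid, "missing value")
            continue
        try:
            b, se = float(cells[0]), float(cells[1])
            n1, n2 = int(float(cells[2])), int(float(cells[3]))
        except (TypeError, ValueError):
            reject(tid, "non-numeric cell")
            continue
        if se <= 0:
            reject(tid, "nonpositive standard error")
            continue
        if n1 < 2 or n2 < 2:
            reject(tid, "arm size below 2")
            continue
        if outcome == "dichotomous":
            if b <= 0:
                reject(tid, "nonpositive dichotomous effect")
                continue
            stat = math.log(b) / se
        else:
            stat = b / se
        nu = n1 + n2 - 2
        records.append({
            "trial_id": tid, "b": b, "se": se, "outcome_type": outcome,
            "n1": n1, "n2": n2, "stat": stat, "nu": nu,
            "p": float(type1_error(abs(stat), nu)),
            "d_assumed": assumed_effect_size(n1, n2),
        })

    records_df = pd.DataFrame(records, columns=[
        "trial_id", "b", "se", "outcome_type", "n1", "n2",
        "stat", "nu", "p", "d_assumed"])
    rejects_df = pd.DataFrame(rejects, columns=["trial_id", "reason"])
    logger.info("loaded corpus: %d records, %d rejects", len(records_df), len(rejects_df))
    return records_df, rejects_df


def filter_corpus(records: pd.DataFrame, *, max_abs_stat: float = MAX_ABS_STAT,
                  min_sample: int = MIN_SAMPLE, size_rule: str = "total"
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the corpus inclusion criteria.

    Excludes trials with ``|stat| >= max_abs_stat`` (reason "extreme
    statistic") and trials failing the sample-size rule (reason "sample
    size below minimum").  ``size_rule`` is ``"total"`` (n1 + n2 >=
    min_sample, the default) or ``"per-arm"`` (each arm >= min_sample).
    Survivor order is preserved; every exclusion carries its reason.
    """
    if size_rule not in ("total", "per-arm"):
        raise ValueError(f"unknown size rule {size_rule!r}")
    extreme = records["stat"].abs() >= max_abs_stat
    if size_rule == "total":
        small = (records["n1"] + records["n2"]) < min_sample
    else:
        small = (records["n1"] < min_sample) | (records["n2"] < min_sample)

    reason = pd.Series("", index=records.index)
    reason[small] = "sample size below minimum"
    reason[extreme] = "extreme statistic"  # takes precedence when both apply
    excluded = records[extreme | small].copy()
    excluded["reason"] = reason[extreme | small]
    kept = records[~(extreme | small)].copy()
    logger.info("filtered corpus: %d kept, %d excluded", len(kept), len(excluded))
    return kept, excluded


def _flexible_thresholds(records: pd.DataFrame, spec: ConstraintSpec, pr: float,
                         C: float, rule: str) -> pd.DataFrame:
    """Per-trial optimal and constrained thresholds (cached by design)."""
    cache: dict[tuple, tuple] = {}
    rows = []
    for n1, n2, d in records[["n1", "n2", "d_assumed"]].itertuples(index=False):
        key = (min(n1, n2), max(n1, n2), d)
        if key not in cache:
            design = StudyDesign(n1=key[0], n2=key[1], d=d, pr=pr, C=C)
            opt = optimize_threshold(design)
            con = optimize_constrained(design, spec, rule=rule)
            cache[key] = (opt.pst_opt, opt.power,
                          con.pst_opt if con.feasible else np.nan,
                          con.power if con.feasible else np.nan)
        rows.append(cache[key])
    return pd.DataFrame(rows, index=records.index,
                        columns=["pst_opt", "power_opt", "c_pst_opt", "power_c"])


def classify_corpus(records: pd.DataFrame, *, criteria=CRITERIA,
                    spec: ConstraintSpec = ConstraintSpec(), pr: float = 0.5,
                    C: float = 0.25, rule: str = "filter") -> pd.DataFrame:
    """Significance calls for every trial under every criterion.

    Significance is strict: significant iff ``p < threshold``.  For the
    constrained criterion, trials whose design is infeasible under the
    constraints are never significant and their threshold is recorded as
    NaN (serialized as "NA").  ``power_at_threshold`` is filled for the
    flexible criteria only.

    Returns a tidy DataFrame with columns trial_id, criterion, threshold,
    significant, power_at_threshold.
    """
    flex = None
    if any(c in FLEXIBLE_CRITERIA for c in criteria):
        flex = _flexible_thresholds(records, spec, pr, C, rule)

    frames = []
    for criterion in criteria:
        if criterion.startswith("fixed_"):
            thr = pd.Series(float(criterion.split("_", 1)[1]), index=records.index)
            power = pd.Series(np.nan, index=records.index)
        elif criterion == "pst_opt":
            thr, power = flex["pst_opt"], flex["power_opt"]
        elif criterion == "c_pst_opt":
            thr, power = flex["c_pst_opt"], flex["power_c"]
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        sig = records["p"] < thr.fillna(0.0)  # NaN threshold -> never significant
        frames.append(pd.DataFrame({
            "trial_id": records["trial_id"], "criterion": criterion,
            "threshold": thr, "significant": sig.astype(bool),
            "power_at_threshold": power,
        }))
        logger.info("criterion %s: %d of %d significant", criterion,
                    int(sig.sum()), len(records))
    return pd.concat(frames, ignore_index=True)


def cohen_kappa(calls_a, calls_b) -> float:
    """Cohen's kappa between two paired binary call vectors.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement ``p_o`` and
    chance agreement ``p_e`` from the raters' marginals.  Undefined (NaN)
    when both raters are constant (``p_e = 1``); exactly 1 for identical
    non-constant vectors.
    """
    a = np.asarray(calls_a, dtype=bool)
    b = np.asarray(calls_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("call vectors must be paired 1-d arrays of equal length")
    if a.size == 0:
        raise ValueError("call vectors are empty")
    p_o = np.mean(a == b)
    pa, pb = a.mean(), b.mean()
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e == 1.0:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def _median_iqr(values: np.ndarray) -> dict:
    """Median and quartiles (linear-interpolation convention)."""
    if values.size == 0:
        return {"median": None, "q1": None, "q3": None}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def summarize_corpus(calls: pd.DataFrame, records: pd.DataFrame, *,
                     kappa_pair: tuple[str, str] = ("pst_opt", "fixed_0.05"),
                     power_bin_width: float = 0.05) -> dict:
    """Corpus-level summary: counts, rates, agreement and distributions.

    Per criterion: count and percentage of significant trials.  Agreement:
    Cohen's kappa between the two ``kappa_pair`` criteria's binary calls.
    For each flexible criterion present: median/IQR of the threshold and of
    the power among its significant trials, plus a power histogram with
    ``power_bin_width``-wide bins over [0, 1].  JSON-serializable.  An
    empty corpus yields an empty summary rather than an error.
    """
    n_total = len(records)
    summary: dict = {"n_total": int(n_total), "criteria": {}}
    if n_total == 0:
        return summary

    by_crit = {c: g.set_index("trial_id") for c, g in calls.groupby("criterion")}
    for criterion, g in by_crit.items():
        count = int(g["significant"].sum())
        summary["criteria"][criterion] = {
            "n_significant": count,
            "pct_significant": 100.0 * count / n_total,
        }

    ka, kb = kappa_pair
    if ka in by_crit and kb in by_crit:
        order = records["trial_id"]
        summary["kappa"] = {
            "criteria": list(kappa_pair),
            "kappa": cohen_kappa(
                by_crit[ka].loc[order, "significant"].to_numpy(),
                by_crit[kb].loc[order, "significant"].to_numpy(),
            ),
        }

    edges = np.arange(0.0, 1.0 + power_bin_width / 2, power_bin_width)
    for criterion in FLEXIBLE_CRITERIA:
        if criterion not in by_crit:
            continue
        g = by_crit[criterion]
        sig = g[g["significant"]]
        thresholds = sig["threshold"].to_numpy(dtype=float)
        powers = sig["power_at_threshold"].to_numpy(dtype=float)
        hist, _ = np.histogram(powers[~np.isnan(powers)], bins=edges)
        summary["criteria"][criterion]["threshold_significant"] = _median_iqr(thresholds)
        summary["criteria"][criterion]["power_significant"] = _median_iqr(powers)
        summary["criteria"][criterion]["power_histogram"] = {
            "bin_edges": [float(e) for e in edges],
            "counts": [int(c) for c in hist],
        }

    if "pst_opt" in by_crit and "fixed_0.05" in by_crit:
        order = records["trial_id"]
        a = by_crit["pst_opt"].loc[order, "significant"].to_numpy()
        b = by_crit["fixed_0.05"].loc[order, "significant"].to_numpy()
        summary["pst_opt_subset_of_fixed_0.05"] = bool(np.all(~a | b))
    return summary
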