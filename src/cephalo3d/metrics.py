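"""Evaluation statistics for 3D landmark detection.

Covers the full endpoint suite: radial error and MRE with normal-theory 95 %
confidence intervals, success detection rate (SDR) at 2/3/4 mm, per-axis
error decomposition with dominant-axis counts, presence confusion with
dental-landmark accuracy/precision (DL-ACC / DL-PRE), consistency ICC(3,1)
from the two-way ANOVA decomposition, a within-observer variability index
based on the 95th-percentile symmetric Hausdorff distance, and the one-sample
t-test sample-size calculation by noncentral-t iteration.

Exclusion rule: a landmark absent in the reference never contributes to
MRE/SDR — it enters only the presence confusion.  SDR uses a strict
inequality (error < threshold); ties have measure zero on continuous data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import LandmarkSet

__all__ = [
    "SDR_THRESHOLDS_MM",
    "radial_error",
    "paired_errors",
    "mre_summary",
    "sdr",
    "axis_decomposition",
    "presence_confusion",
    "icc31",
    "wovi_hd95",
    "sample_size_one_sample_t",
    "EvalReport",
    "report",
    "manifest_rollup",
]

SDR_THRESHOLDS_MM = (2.0, 3.0, 4.0)
AXES = ("x", "y", "z")


def radial_error(pred_mm, truth_mm) -> float:
    """Euclidean distance in mm between a predicted and a reference point."""
    pred_mm = np.asarray(pred_mm, float)
    truth_mm = np.asarray(truth_mm, float)
    if not (np.all(np.isfinite(pred_mm)) and np.all(np.isfinite(truth_mm))):
        raise ValueError("radial error requires both points present")
    return float(np.linalg.norm(pred_mm - truth_mm))


def paired_errors(pred: LandmarkSet, truth: LandmarkSet):
    """Per-landmark records for one case, applying the exclusion rule.

    Returns a list of dicts with name, radial error and per-axis absolute
    deviations for landmarks present in BOTH sets.  Landmarks absent in the
    truth are excluded from error metrics (they count in presence confusion
    only); landmarks present in truth but missed by the prediction contribute
    no error record either (they surface as false negatives).
    """
    records = []
    for name, t in truth.entries.items():
        if not t.present or name not in pred.entries:
            continue
        p = pred.entries[name]
        if not p.present:
            continue
        delta = np.abs(np.asarray(p.coord) - np.asarray(t.coord))
        records.append({
            "name": name,
            "radial": float(np.linalg.norm(p.coord - t.coord)),
            "dx": float(delta[0]), "dy": float(delta[1]), "dz": float(delta[2]),
        })
    return records


def mre_summary(errors: Sequence[float]) -> dict:
    """Mean radial error with sample SD and normal-theory 95 % CI.

    SD uses the n-1 denominator; CI = mean +/- 1.96 * SD / sqrt(n).  With a
    single error the SD and CI are undefined (NaN).
    """
    e = np.asarray(list(errors), float)
    if e.size == 0:
        raise ValueError("no errors to summarize")
    mean = float(e.mean())
    if e.size < 2:
        return {"n": 1, "mean": mean, "sd": float("nan"),
                "ci95": (float("nan"), float("nan"))}
    sd = float(e.std(ddof=1))
    half = 1.96 * sd / np.sqrt(e.size)
    return {"n": int(e.size), "mean": mean, "sd": sd,
            "ci95": (mean - half, mean + half)}


def sdr(errors: Sequence[float], thresholds: Sequence[float] = SDR_THRESHOLDS_MM) -> dict:
    """Success detection rate: 100 * #{e < t} / n for each threshold (mm)."""
    e = np.asarray(list(errors), float)
    if e.size == 0:
        raise ValueError("SDR undefined for an empty error list")
    thresholds = tuple(thresholds)
    if any(t <= 0 for t in thresholds) or list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be positive and sorted")
    return {t: float(100.0 * np.mean(e < t)) for t in thresholds}


def axis_decomposition(records: Sequence[Mapping]) -> dict:
    """Per-axis |delta| summaries and per-landmark dominant-axis counts.

    For each catalog landmark the dominant axis is the one with the largest
    mean absolute error (ties broken toward the earlier axis in x, y, z
    order).  Fractions are percentages over the distinct landmarks observed.
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame(list(records))
    per_axis = {a: {"mean": float(df[f"d{a}"].mean()), "sd": float(df[f"d{a}"].std(ddof=1))
                    if len(df) > 1 else float("nan")} for a in AXES}
    by_lm = df.groupby("name")[[f"d{a}" for a in AXES]].mean()
    dominant = by_lm.to_numpy().argmax(axis=1)  # argmax takes the first max: x<y<z tie-break
    counts = {a: int((dominant == i).sum()) for i, a in enumerate(AXES)}
    n_lm = len(by_lm)
    fractions = {a: 100.0 * counts[a] / n_lm for a in AXES}
    dom_axis = {lm: AXES[d] for lm, d in zip(by_lm.index, dominant)}
    return {"per_axis": per_axis, "dominant_counts": counts,
            "dominant_fractions": fractions, "dominant_axis": dom_axis,
            "n_landmarks": n_lm}


def presence_confusion(pred_sets: Sequence[LandmarkSet], truth_sets: Sequence[LandmarkSet],
                       dental: Iterable[str], positional_tp_mm: float | None = None) -> dict:
    """Dental presence classification over all (case, dental landmark) pairs.

    TP: truth-present predicted-present; TN: truth-absent predicted-absent;
    FP: truth-absent predicted-present; FN: truth-present predicted-absent.
    DL-ACC = 100 (TP+TN)/(TP+TN+FP+FN); DL-PRE = 100 TP/(TP+FP), NaN-flagged
    when no positive predictions exist.  With ``positional_tp_mm`` set, a
    predicted-present landmark only counts as TP if its radial error is below
    that bound (otherwise it becomes FP).
    """
    dental = list(dental)
    tp = tn = fp = fn = 0
    for pred, truth in zip(pred_sets, truth_sets, strict=True):
        for name in dental:
            if name not in truth.entries:
                continue
            t = truth.entries[name]
            p_present = name in pred.entries and pred.entries[name].present
            if t.present and p_present:
                if positional_tp_mm is not None and (
                        radial_error(pred.entries[name].coord, t.coord) >= positional_tp_mm):
                    fp += 1
                else:
                    tp += 1
            elif t.present and not p_present:
                fn += 1
            elif not t.present and p_present:
                fp += 1
            else:
                tn += 1
    total = tp + tn + fp + fn
    acc = 100.0 * (tp + tn) / total if total else float("nan")
    pre = 100.0 * tp / (tp + fp) if (tp + fp) else float("nan")
    return {"TP": tp, "TN": tn, "FP": fp, "FN": fn,
            "dl_acc": acc, "dl_pre": pre}


def icc31(matrix) -> float:
    """Consistency ICC(3,1) from the two-way mixed-model ANOVA decomposition.

    ``matrix`` is n targets x k raters, no missing cells.
    ICC = (MS_rows - MS_error) / (MS_rows + (k-1) MS_error); rater offsets do
    not affect it.  Requires n >= 3, k >= 2 and non-zero between-target
    variance.
    """
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 3 targets, k >= 2 raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing cells are not supported")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows + (k - 1) * ms_err <= 0:
        raise ValueError("zero between-target variance; ICC undefined")
    return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))


def _hd95(a: np.ndarray, b: np.ndarray) -> float:
    """95th-percentile symmetric Hausdorff distance between two point sets."""
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    directed = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(directed, 95))


def wovi_hd95(sessions_a: Sequence[np.ndarray], sessions_b: Sequence[np.ndarray]) -> dict:
    """Within-observer variability: per-case HD95 between two annotation
    sessions, aggregated as mean with a normal-theory 95 % CI.

    Empty point sets are excluded and recorded.  Symmetric in (A, B).
    """
    values, excluded = [], 0
    for a, b in zip(sessions_a, sessions_b, strict=True):
        a, b = np.atleast_2d(np.asarray(a, float)), np.atleast_2d(np.asarray(b, float))
        if a.size == 0 or b.size == 0:
            excluded += 1
            continue
        values.append(_hd95(a, b))
    if not values:
        raise ValueError("no non-empty session pairs")
    summ = mre_summary(values)
    return {"per_case": values, "mean": summ["mean"], "ci95": summ["ci95"],
            "excluded_cases": excluded}


def sample_size_one_sample_t(delta: float, sd: float, alpha: float = 0.05,
                             power: float = 0.90, n_max: int = 100000) -> int:
    """Smallest n for a two-sided one-sample t-test to reach target power.

    Detecting a shift ``delta`` given standard deviation ``sd``: power is
    evaluated exactly from the noncentral-t distribution with noncentrality
    sqrt(n) * delta / sd, iterating over n.
    """
    if delta <= 0 or sd <= 0 or not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("require delta, sd > 0 and alpha, power in (0,1)")
    for n in range(2, n_max + 1):
        df = n - 1
        nc = np.sqrt(n) * delta / sd
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        achieved = (1.0 - stats.nct.cdf(tcrit, df, nc)
                    + stats.nct.cdf(-tcrit, df, nc))
        if achieved >= power:
            return n
    raise RuntimeError("sample size search did not converge")


# ---------------------------------------------------------------------------
# aggregated report


@dataclass
class EvalReport:
    """Aggregated metric bundle across cases and strata."""

    overall: dict
    by_scenario: dict
    by_tissue: dict
    by_region: dict
    axis: dict
    presence: dict
    manifest: dict = field(default_factory=dict)
    per_case: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        """Stratum rows with MRE ± SD, CI and SDR columns."""
        rows = []
        for stratum, d in [("Overall", self.overall), *self.by_scenario.items(),
                           *self.by_tissue.items(), *self.by_region.items()]:
            rows.append({"stratum": stratum, "n": d["mre"]["n"],
                         "MRE": d["mre"]["mean"], "SD": d["mre"]["sd"],
                         "CI_lo": d["mre"]["ci95"][0], "CI_hi": d["mre"]["ci95"][1],
                         **{f"SDR_{int(t)}mm": v for t, v in d["sdr"].items()}})
        return pd.DataFrame(rows)


def _stratum_stats(errors: Sequence[float]) -> dict:
    return {"mre": mre_summary(errors), "sdr": sdr(errors)}


def report(predictions: Sequence[LandmarkSet], truths: Sequence[LandmarkSet],
           catalog, scenarios: Sequence[str] | None = None,
           manifest: Mapping | None = None) -> EvalReport:
    """Full evaluation over matched case lists.

    ``catalog`` supplies tissue/region groupings and the dental subset;
    ``scenarios`` (one label per case, e.g. Normal/M/MDL/MA) enables
    per-scenario strata; ``manifest`` rows are rolled up via
    :func:`manifest_rollup`.
    """
    pred_ids = [p.case_id for p in predictions]
    truth_ids = [t.case_id for t in truths]
    if pred_ids != truth_ids:
        unmatched = sorted(set(pred_ids) ^ set(truth_ids))
        raise ValueError(f"case lists differ; unmatched ids: {unmatched}")
    scenarios = list(scenarios) if scenarios is not None else ["All"] * len(truths)
    tissue = {d.name: d.tissue for d in catalog}
    region = {d.name: d.region for d in catalog}
    dental = [d.name for d in catalog if d.tissue == "dental"]

    rows = []
    for pred, truth, scen in zip(predictions, truths, scenarios):
        for rec in paired_errors(pred, truth):
            rows.append({**rec, "case": truth.case_id, "scenario": scen,
                         "tissue": tissue.get(rec["name"], "bone"),
                         "region": region.get(rec["name"], "middle-third")})
    if not rows:
        raise ValueError("no overlapping present landmarks to evaluate")
    df = pd.DataFrame(rows)

    def strata(col):
        return {key: _stratum_stats(sub["radial"]) for key, sub in df.groupby(col)}

    return EvalReport(
        overall=_stratum_stats(df["radial"]),
        by_scenario=strata("scenario") if scenarios else {},
        by_tissue=strata("tissue"),
        by_region=strata("region"),
        axis=axis_decomposition(rows),
        presence=presence_confusion(predictions, truths, dental),
        manifest=manifest_rollup(manifest) if manifest else {},
        per_case=df,
    )


def manifest_rollup(manifest: Mapping) -> dict:
    """Pool per-center dataset counts and demographics.

    ``manifest`` maps center name -> dict with ``n`` (case count) and
    optionally ``male``, ``mean_age``, and per-scenario counts (``M``,
    ``MDL``, ``MA``).  Returns totals, the count-weighted pooled mean age,
    and the male percentage.
    """
    centers = list(manifest.values())
    total = int(sum(c["n"] for c in centers))
    out: dict = {"total_cases": total, "centers": len(centers)}
    if all("male" in c for c in centers):
        male = int(sum(c["male"] for c in centers))
        out["male"] = male
        out["pct_male"] = 100.0 * male / total
    if all("mean_age" in c for c in centers):
        out["pooled_mean_age"] = float(
            sum(c["n"] * c["mean_age"] for c in centers) / total)
    for key in ("M", "MDL", "MA"):
        if all(key in c for c in centers):
            out[f"total_{key}"] = int(sum(c[key] for c in centers))
    return out
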