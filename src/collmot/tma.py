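"""Patient-level scoring of multiplexed tissue-microarray cell tables and
survival stratification.

The pipeline mirrors standard multiplexed-immunohistochemistry practice:

1. exclude patients with fewer than ``min_cells`` quantified cells in the
   stromal or the epithelial compartment;
2. aggregate per-cell intensities to patient level, pooling all cores of a
   patient: median stromal extranuclear intensity for each of the five ECM
   markers (fibronectin, collagen I, SMA, laminin, vinculin) and mean
   nuclear YAP in the tumour epithelium;
3. assign each patient one ECM point per marker strictly above the
   across-patient median, yielding a 0-5 ECM score (0-2 = ECM-low,
   3-5 = ECM-high) and a median-split YAP-high/low class;
4. compare groups with the Kaplan-Meier product-limit estimator and the
   two-group log-rank test, both implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

ECM_MARKERS = ("fibronectin", "collagen_I", "SMA", "laminin", "vinculin")
YAP_MARKER = "YAP"
BCAT_MARKER = "beta_catenin"
COMPARTMENTS = ("epithelial", "stromal")

CELL_COLUMNS = ("patient_id", "core_id", "compartment", "marker",
                "nuclear_mean", "extranuclear_mean")


@dataclass
class ExclusionReport:
    """Patients removed by the minimum-cell-count rule."""

    min_cells: int
    counts: pd.DataFrame  # patient_id, stromal_cells, epithelial_cells, excluded
    excluded_ids: list[str]
    n_retained: int


def _check_schema(cells: pd.DataFrame) -> None:
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")


def _cell_counts(cells: pd.DataFrame) -> pd.DataFrame:
    """Cells per patient and compartment, robust to long-format marker rows."""
    if "cell_id" in cells.columns:
        counts = (
            cells.groupby(["patient_id", "compartment"])
            .apply(lambda g: g[["core_id", "cell_id"]].drop_duplicates().shape[0],
                   include_groups=False)
            .unstack(fill_value=0)
        )
    else:
        n_markers = cells["marker"].nunique()
        counts = (
            cells.groupby(["patient_id", "compartment"]).size().unstack(fill_value=0)
            // max(n_markers, 1)
        )
    for comp in COMPARTMENTS:
        if comp not in counts.columns:
            counts[comp] = 0
    return counts[list(COMPARTMENTS)]


def exclude_low_cell_patients(
    cells: pd.DataFrame, min_cells: int = 100
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop patients with fewer than ``min_cells`` cells in the stromal OR
    the epithelial compartment (boundary inclusive: exactly ``min_cells``
    is retained)."""
    _check_schema(cells)
    if len(cells) == 0:
        raise ValueError("cell table is empty")
    counts = _cell_counts(cells)
    excluded = counts[(counts["stromal"] < min_cells) | (counts["epithelial"] < min_cells)]
    excluded_ids = sorted(excluded.index)
    filtered = cells[~cells["patient_id"].isin(excluded_ids)].copy()
    report = ExclusionReport(
        min_cells=min_cells,
        counts=counts.rename(
            columns={"stromal": "stromal_cells", "epithelial": "epithelial_cells"}
        ).assign(excluded=counts.index.isin(excluded_ids)).reset_index(),
        excluded_ids=excluded_ids,
        n_retained=counts.shape[0] - len(excluded_ids),
    )
    return filtered, report


def patient_aggregate(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-patient summaries, pooling all cores of a patient.

    Returns a DataFrame indexed by patient_id with one column per ECM
    marker (median stromal extranuclear intensity), ``yap_nuclear`` (mean
    nuclear YAP over epithelial cells) and, when a 'beta_catenin' marker is
    present, ``bcat_junctional`` (mean epithelial extranuclear intensity).
    """
    _check_schema(cells)
    present = set(cells["marker"].unique())
    missing = [m for m in ECM_MARKERS if m not in present]
    if missing or YAP_MARKER not in present:
        raise ValueError(f"cell table missing markers: {missing + ([YAP_MARKER] if YAP_MARKER not in present else [])}")
    stromal = cells[(cells["compartment"] == "stromal") & cells["marker"].isin(ECM_MARKERS)]
    ecm = (
        stromal.groupby(["patient_id", "marker"])["extranuclear_mean"]
        .median()
        .unstack()[list(ECM_MARKERS)]
    )
    epi_yap = cells[(cells["compartment"] == "epithelial") & (cells["marker"] == YAP_MARKER)]
    summary = ecm.join(
        epi_yap.groupby("patient_id")["nuclear_mean"].mean().rename("yap_nuclear"),
        how="outer",
    )
    if BCAT_MARKER in present:
        epi_bcat = cells[
            (cells["compartment"] == "epithelial") & (cells["marker"] == BCAT_MARKER)
        ]
        summary = summary.join(
            epi_bcat.groupby("patient_id")["extranuclear_mean"].mean().rename("bcat_junctional"),
            how="left",
        )
    return summary


def ecm_score(summaries: pd.DataFrame) -> pd.DataFrame:
    """ECM score 0-5 and low/high class from per-patient summaries.

    For each marker the threshold is the across-patient median of the
    patient-level values; a patient earns one point per marker *strictly*
    above its threshold (a value exactly at the median scores 0 for that
    marker).  Scores 0-2 are 'low', 3-5 'high'.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 patients to define dataset medians")
    thresholds = summaries[list(ECM_MARKERS)].median(axis=0)
    points = summaries[list(ECM_MARKERS)].gt(thresholds, axis=1)
    score = points.sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "ecm_score": score,
            "ecm_group": np.where(score <= 2, "low", "high"),
        },
        index=summaries.index,
    )


def yap_group(summaries: pd.DataFrame) -> pd.DataFrame:
    """YAP-high/low class: strictly above the dataset median of mean
    nuclear YAP in the tumour epithelium."""
    if len(summaries) < 2:
        raise ValueError("need at least 2 patients to define the dataset median")
    thr = summaries["yap_nuclear"].median()
    return pd.DataFrame(
        {"yap_group": np.where(summaries["yap_nuclear"] > thr, "high", "low")},
        index=summaries.index,
    )


def score_cohort(
    cells: pd.DataFrame, min_cells: int = 100
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Full scoring pipeline: exclusion filter, aggregation, ECM + YAP
    classes.  Returns (scored cohort indexed by patient_id, report)."""
    filtered, report = exclude_low_cell_patients(cells, min_cells)
    summaries = patient_aggregate(filtered)
    scored = summaries.join(ecm_score(summaries)).join(yap_group(summaries))
    return scored, report


# --------------------------------------------------------------------------
# survival
# --------------------------------------------------------------------------


@dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate.

    ``time`` starts at 0 with S(0) = 1; subsequent entries are the distinct
    event times with the post-event survival, at-risk count and number of
    events.  Ties at a time are processed events-before-censorings.
    """

    time: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.time, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_estimate(times, events) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator with right censoring."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("need at least one record")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    if not np.all(np.isin(e, [0, 1])):
        raise ValueError("event indicator must be 0 or 1")
    event_times = np.unique(t[e == 1])
    surv, n_risk, n_event = [1.0], [len(t)], [0]
    out_t = [0.0]
    s = 1.0
    for ti in event_times:
        at_risk = int(np.sum(t >= ti))  # censorings at ti still at risk
        d = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d / at_risk
        out_t.append(float(ti))
        surv.append(s)
        n_risk.append(at_risk)
        n_event.append(d)
    return KaplanMeierCurve(
        time=np.array(out_t),
        survival=np.array(surv),
        at_risk=np.array(n_risk),
        events=np.array(n_event),
    )


@dataclass
class LogrankResult:
    statistic: float  # chi-square, 1 df
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def logrank_test(times, events, groups) -> LogrankResult:
    """Two-group log-rank test (observed minus expected, hypergeometric
    variance with ties, no continuity correction)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    if (g == labels[0]).sum() == 0 or (g == labels[1]).sum() == 0:
        raise ValueError("one group is empty")
    if e.sum() == 0:
        raise ValueError("need at least one event")
    in1 = g == labels[0]
    o1 = ex1 = var = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        d = int(((t == ti) & (e == 1)).sum())
        d1 = int(((t == ti) & (e == 1) & in1).sum())
        o1 += d1
        ex1 += n1 * d / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return LogrankResult(0.0, 1.0, (o1, e.sum() - o1), (ex1, e.sum() - ex1))
    stat = (o1 - ex1) ** 2 / var
    return LogrankResult(
        statistic=float(stat),
        p_value=float(chi2.sf(stat, df=1)),
        observed=(float(o1), float(e.sum() - o1)),
        expected=(float(ex1), float(e.sum() - ex1)),
    )


def compare_survival(
    scored: pd.DataFrame,
    survival: pd.DataFrame,
    by: str = "ecm_group",
) -> tuple[dict[str, KaplanMeierCurve], LogrankResult]:
    """Join a scored cohort to survival records and compare the two
    classes of ``by`` (e.g. 'ecm_group' or 'yap_group')."""
    merged = survival.merge(
        scored[[by]], left_on="patient_id", right_index=True, how="inner"
    )
    curves = {
        label: km_estimate(sub["time_months"], sub["event"])
        for label, sub in merged.groupby(by)
    }
    result = logrank_test(merged["time_months"], merged["event"], merged[by])
    return curves, result
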