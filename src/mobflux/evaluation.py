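"""Model comparison: DIC ranking, ratio-of-prediction accuracy, OD proportions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geography import ValidationError
from .inference import FitResult
from .trips import TripMatrix
from .typology import K_LABELS, M_LABELS, N_LABELS, TripTypology


def od_proportions(trips: TripMatrix) -> TripMatrix:
    """Row-normalize a trip matrix: each origin's trips as proportions of its outflow.

    Rows with zero total (or no observed routes) come back all-NaN.
    """
    v = trips.values
    if np.any(v[np.isfinite(v)] < 0):
        raise ValidationError("trip counts must be non-negative")
    sums = np.nansum(v, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(sums > 0, v / sums, np.nan)
    return TripMatrix(list(trips.ids), out)


def percent_change_dic(dic_model: float, dic_basic: float) -> float:
    """Percent DIC change relative to the basic model; positive = improvement."""
    if dic_basic == 0:
        raise ValidationError("basic-model DIC of zero makes percent change undefined")
    return 100.0 * (dic_basic - dic_model) / dic_basic


def ratio_accuracy(
    pred: TripMatrix,
    obs: TripMatrix,
    typology: TripTypology | None = None,
    margin: float = 0.10,
) -> pd.DataFrame:
    """Per-trip-type prediction accuracy from the ratio of predicted to observed counts.

    For each category (overall, plus each urbanicity k, regional m, and
    regional-urbanicity n cell when a typology is given) reports the number
    of comparable routes, quantiles of pred/obs, and the fraction of routes
    whose prediction falls within ``margin`` (default +-10%) of the observed
    count. Routes with observed count 0 have an undefined ratio; they are
    excluded and counted in ``n_excluded_zero_obs``.
    """
    if margin <= 0:
        raise ValidationError("margin must be positive")
    pred = pred.align_to(obs.ids)
    mask = obs.observed_mask & np.isfinite(pred.values)
    pos = mask & (obs.values > 0)
    ratio = np.full(obs.values.shape, np.nan)
    ratio[pos] = pred.values[pos] / obs.values[pos]

    def summarize(cell_mask: np.ndarray, label: str, scheme: str, category) -> dict:
        r = ratio[cell_mask & pos]
        within = np.abs(r - 1.0) <= margin
        return {
            "scheme": scheme,
            "category": category,
            "label": label,
            "n_routes": int(r.size),
            "n_excluded_zero_obs": int(np.sum(cell_mask & mask & (obs.values == 0))),
            "median_ratio": float(np.median(r)) if r.size else np.nan,
            "q25_ratio": float(np.quantile(r, 0.25)) if r.size else np.nan,
            "q75_ratio": float(np.quantile(r, 0.75)) if r.size else np.nan,
            "accuracy": float(np.mean(within)) if r.size else np.nan,
        }

    rows = [summarize(np.ones_like(mask), "overall", "overall", 0)]
    if typology is not None:
        if typology.ids != obs.ids:
            raise ValidationError("typology does not match the trip matrices")
        for k, lab in K_LABELS.items():
            rows.append(summarize(typology.k_index == k, lab, "urbanicity", k))
        for m, lab in M_LABELS.items():
            rows.append(summarize(typology.m_index == m, lab, "regional", m))
        for n, lab in N_LABELS.items():
            rows.append(summarize(typology.n_index == n, lab, "regional_urbanicity", n))
    return pd.DataFrame(rows)


def rank_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fitted models by ascending DIC (ties broken by fewer parameters).

    Includes the percent DIC change relative to the basic gravity model when
    one is present. All fits must be on the same observed data.
    """
    if len(fits) < 2:
        raise ValidationError("ranking needs at least two fitted models")
    keys = {(f.data_n_routes, round(f.data_total, 6)) for f in fits}
    if len(keys) > 1:
        raise ValidationError("fits were made on different observed data; ranking is meaningless")
    basic = next((f for f in fits if f.model == "gravity" and f.scheme == "basic"), None)
    rows = [
        {
            "model": f.label,
            "kernel": f.kernel,
            "dic": f.dic,
            "p_d": f.p_d,
            "n_parameters": f.n_parameters,
            "pct_change_vs_basic": percent_change_dic(f.dic, basic.dic) if basic else np.nan,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values(["dic", "n_parameters"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


@dataclass
class EvaluationReport:
    """DIC table, per-trip-type ratio/accuracy tables, and OD proportion matrices."""

    dic_table: pd.DataFrame
    accuracy_tables: dict[str, pd.DataFrame]  # model label -> ratio_accuracy table
    proportions: dict[str, TripMatrix]        # "observed" + model labels
    margin: float = 0.10

    def to_json_dict(self) -> dict:
        return {
            "margin": self.margin,
            "dic_table": self.dic_table.to_dict(orient="records"),
            "accuracy": {
                k: v.to_dict(orient="records") for k, v in sorted(self.accuracy_tables.items())
            },
        }


def evaluate_models(
    fits: Sequence[FitResult],
    predictions: Mapping[str, TripMatrix],
    obs: TripMatrix,
    typology: TripTypology | None = None,
    margin: float = 0.10,
) -> EvaluationReport:
    """Assemble the full comparison report for a set of fitted models."""
    dic_table = rank_models(fits)
    acc = {label: ratio_accuracy(pred, obs, typology, margin) for label, pred in predictions.items()}
    props = {"observed": od_proportions(obs)}
    for label, pred in predictions.items():
        props[label] = od_proportions(pred)
    return EvaluationReport(dic_table=dic_table, accuracy_tables=acc, proportions=props, margin=margin)


def plot_proportion_heatmaps(report: EvaluationReport, path, labels: Sequence[str] | None = None) -> None:
    """Side-by-side heatmaps of observed vs modeled OD proportion matrices (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(labels) if labels is not None else list(report.proportions)
    fig, axes = plt.subplots(1, len(labels), figsize=(4 * len(labels), 4), squeeze=False)
    for ax, label in zip(axes[0], labels):
        v = report.proportions[label].values
        im = ax.imshow(np.nan_to_num(v), cmap="Blues", vmin=0, vmax=np.nanmax(v))
        ax.set_title(label)
        ax.set_xlabel("destination")
        ax.set_ylabel("origin")
        fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
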