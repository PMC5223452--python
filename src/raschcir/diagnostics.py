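"""Structured data behind the three diagnostic displays, and their rendering.

* Wright map — the person-measure histogram and the item difficulties share
  one logit axis; each item carries its INFIT mean square so departures from
  a single underlying construct are visible at a glance.
* Box-plot KIDMAP — one focal person against the cohort: per item, the
  cohort's five-number response summary, the focal response, and the focal
  standardized residual; items with Z >= +2 are strengths, Z <= -2
  weaknesses, relative to the counterparts.
* ICC overlay — the model expectation curve over theta - delta with each
  person plotted at (measure, OUTFIT) and a reference line at OUTFIT = 2.

Builders are pure functions of the fit; tests target the JSON form of these
structures rather than rendered pixels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import FitResult, rasch_probability
from .fitstats import (CELL_Z_THRESHOLD, ITEM_INFIT_THRESHOLD,
                       PERSON_OUTFIT_THRESHOLD, FitStatistics)

__all__ = [
    "WrightMapData",
    "KidmapData",
    "ICCOverlayData",
    "build_wright_map",
    "build_kidmap",
    "build_icc_overlay",
    "render",
]


@dataclass
class WrightMapData:
    bin_edges: list
    person_bins: list
    item_points: list  # (item_id, difficulty, infit, fits_construct)
    shared_axis: tuple
    single_construct: bool
    bin_width: float


@dataclass
class KidmapData:
    focal_person: str
    theta: float
    outfit: float
    misfit: bool
    per_item: list  # dicts: item, difficulty, response, cohort box, z
    strengths: list
    weaknesses: list


@dataclass
class ICCOverlayData:
    curve_x: list  # theta - delta grid
    curve_p: list
    person_points: list  # (person_id, theta, outfit, flagged)
    flag_line: float


def build_wright_map(fit: FitResult, stats: FitStatistics,
                     bin_width: float = 0.25) -> WrightMapData:
    """Bin non-extreme person measures at ``bin_width`` logits and pair each
    non-extreme item with its difficulty and INFIT mean square."""
    if bin_width <= 0:
        raise ValueError("bin_width must be strictly positive")
    keep_p = ~fit.extreme_person_flags
    keep_i = ~fit.extreme_item_flags
    theta = fit.theta[keep_p]
    if theta.size == 0:
        raise ValueError("no non-extreme persons to map")
    delta = fit.delta[keep_i]
    lo = min(theta.min(), delta.min())
    hi = max(theta.max(), delta.max())
    first = np.floor(lo / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((hi - first) / bin_width + 1e-9)))
    edges = first + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(theta, bins=edges)
    infit = stats.item_infit[keep_i]
    items = [
        (str(i), float(d), float(f), bool(f < ITEM_INFIT_THRESHOLD))
        for i, d, f in zip(np.asarray(fit.item_ids, dtype=object)[keep_i],
                           delta, infit)
    ]
    return WrightMapData(
        bin_edges=[float(e) for e in edges],
        person_bins=[int(c) for c in counts],
        item_points=items,
        shared_axis=(float(edges[0]), float(edges[-1])),
        single_construct=bool(np.all(infit < ITEM_INFIT_THRESHOLD)),
        bin_width=float(bin_width),
    )


def _five_numbers(values: np.ndarray) -> dict:
    q = np.percentile(values, [0, 25, 50, 75, 100])
    return {"min": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
            "q3": float(q[3]), "max": float(q[4])}


def build_kidmap(fit: FitResult, stats: FitStatistics, person) -> KidmapData:
    """Per-item cohort box summaries with the focal person's responses and
    standardized residuals; the +/-2 rule fills the strength/weakness lists."""
    n = fit.person_index(person)
    x = fit.rescaled.values
    z = fit.residuals.Z
    per_item = []
    strengths: list = []
    weaknesses: list = []
    for j, item in enumerate(fit.item_ids):
        col = x[:, j]
        cohort = col[~np.isnan(col)]
        focal_x = x[n, j]
        focal_z = z[n, j]
        entry = {
            "item": str(item),
            "difficulty": float(fit.delta[j]),
            "response": None if np.isnan(focal_x) else float(focal_x),
            "cohort": _five_numbers(cohort),
            "z": None if np.isnan(focal_z) else float(focal_z),
        }
        per_item.append(entry)
        if entry["z"] is not None:
            if entry["z"] >= CELL_Z_THRESHOLD:
                strengths.append(str(item))
            elif entry["z"] <= -CELL_Z_THRESHOLD:
                weaknesses.append(str(item))
    outfit = float(stats.person_outfit[n])
    return KidmapData(
        focal_person=str(person),
        theta=float(fit.theta[n]),
        outfit=outfit,
        misfit=bool(outfit >= PERSON_OUTFIT_THRESHOLD),
        per_item=per_item,
        strengths=strengths,
        weaknesses=weaknesses,
    )


def build_icc_overlay(fit: FitResult, stats: FitStatistics,
                      n_points: int = 201) -> ICCOverlayData:
    """Sample the logistic expectation curve over the fitted theta - delta
    range (padded by one logit) and place persons at (measure, OUTFIT)."""
    diff = fit.theta[:, None] - fit.delta[None, :]
    lo = float(diff.min()) - 1.0
    hi = float(diff.max()) + 1.0
    grid = np.linspace(lo, hi, n_points)
    curve = rasch_probability(grid, 0.0)
    points = [
        (str(p), float(t), float(o), bool(f))
        for p, t, o, f in zip(fit.person_ids, fit.theta, stats.person_outfit,
                              stats.person_misfit_flags)
    ]
    return ICCOverlayData(
        curve_x=[float(v) for v in grid],
        curve_p=[float(v) for v in curve],
        person_points=points,
        flag_line=PERSON_OUTFIT_THRESHOLD,
    )


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def render(data, path, format: str | None = None) -> Path:
    """Write a diagnostic object as json (the exact structured data) or as a
    deterministic svg/png figure."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        payload = {"kind": type(data).__name__, "data": _to_jsonable(data)}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path
    if fmt not in ("svg", "png"):
        raise ValueError(f"unknown render format {fmt!r}; use svg, png or json")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(data, WrightMapData):
        fig, (ax_p, ax_i) = plt.subplots(
            1, 2, sharey=True, figsize=(7, 5),
            gridspec_kw={"width_ratios": [2, 1]})
        centers = (np.asarray(data.bin_edges[:-1]) +
                   np.asarray(data.bin_edges[1:])) / 2
        ax_p.barh(centers, data.person_bins, height=data.bin_width * 0.9,
                  color="#4878a8")
        ax_p.invert_xaxis()
        ax_p.set_xlabel("persons")
        ax_p.set_ylabel("logits")
        for item, d, infit, ok in data.item_points:
            ax_i.plot(infit, d, "o", color="#2a7d46" if ok else "#b03a2e")
            ax_i.annotate(item, (infit, d), fontsize=7,
                          textcoords="offset points", xytext=(4, 0))
        ax_i.axvline(ITEM_INFIT_THRESHOLD, ls="--", color="gray")
        ax_i.set_xlabel("item INFIT MNSQ")
        fig.suptitle("Wright map")
    elif isinstance(data, KidmapData):
        fig, ax = plt.subplots(figsize=(7, 5))
        stats_list = []
        for entry in data.per_item:
            c = entry["cohort"]
            stats_list.append({
                "med": c["median"], "q1": c["q1"], "q3": c["q3"],
                "whislo": c["min"], "whishi": c["max"],
                "label": entry["item"], "fliers": [],
            })
        ax.bxp(stats_list, showfliers=False)
        for pos, entry in enumerate(data.per_item, start=1):
            if entry["response"] is not None:
                color = ("#2a7d46" if entry["item"] in data.strengths else
                         "#b03a2e" if entry["item"] in data.weaknesses else
                         "#333333")
                ax.plot(pos, entry["response"], "D", color=color)
                if entry["z"] is not None:
                    ax.annotate(f"Z={entry['z']:.2f}",
                                (pos, entry["response"]), fontsize=7,
                                textcoords="offset points", xytext=(5, 5))
        ax.set_ylabel("unit-interval response")
        ax.set_title(f"KIDMAP: {data.focal_person} "
                     f"(theta={data.theta:.2f}, OUTFIT={data.outfit:.2f})")
        plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    elif isinstance(data, ICCOverlayData):
        fig, ax = plt.subplots(figsize=(7, 5))
        ax.plot(data.curve_x, data.curve_p, color="#4878a8",
                label="model expectation")
        ax2 = ax.twinx()
        for _, t, o, flagged in data.person_points:
            ax2.plot(t, o, "o", color="#b03a2e" if flagged else "#666666",
                     markersize=4)
        ax2.axhline(data.flag_line, ls="--", color="gray")
        ax.set_xlabel("theta - delta (logits)")
        ax.set_ylabel("expected response")
        ax2.set_ylabel("person OUTFIT MNSQ")
        ax.set_title("Item characteristic curve with person OUTFIT overlay")
    else:
        raise TypeError(f"cannot render object of type {type(data).__name__}")

    fig.tight_layout()
    fig.savefig(path, format=fmt, metadata={"Date": None} if fmt == "svg" else None)
    plt.close(fig)
    return path
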