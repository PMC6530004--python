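"""Divergence landscapes, activity peaks, and the cross-species event report.

Percent divergence of a copy from its subfamily consensus is a molecular
clock: the higher the divergence, the older the insertion.  Per family and
species, assigned copies are histogrammed in 1% bins, smoothed with a
Gaussian kernel of 0.4 percentage-point bandwidth, and summarized by the
smoothed peak.  Copy numbers are normalized to copies per 3 Gbp of searched
sequence, which approximates copies per haploid genome at these genome sizes.

The event report orders families oldest-first by mean peak and derives the
qualitative history: cross-species synchrony of shared families, coincident
activity of different elements, copy-number asymmetries between species, and
per-species extinction calls (an element is called extinct in a species when
no family present there has a peak more recent than the recency threshold).
Extinction is a call on the *absence* of recent families and therefore
depends on the detection floor; the report records that floor next to every
call.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .copyassign import AssignmentTable

GRID_STEP = 0.01
GRID_MAX = 50.0
DEFAULT_BANDWIDTH = 0.4


@dataclass
class DivergenceProfile:
    group_id: str
    species: str
    histogram: np.ndarray  # counts per 1% bin over [0, 50)
    kde_grid: np.ndarray
    kde: np.ndarray
    peak: float  # argmax of the KDE (percent); nan for empty profiles
    raw_count: int
    copies_per_3gbp: float

    @property
    def empty(self) -> bool:
        return self.raw_count == 0


def gaussian_kde_profile(
    values: np.ndarray, bandwidth: float = DEFAULT_BANDWIDTH, grid_step: float = GRID_STEP
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-bandwidth Gaussian KDE evaluated on the divergence grid."""
    grid = np.arange(0.0, GRID_MAX + grid_step / 2, grid_step)
    if len(values) == 0:
        return grid, np.zeros_like(grid)
    z = (grid[None, :] - values[:, None]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=0) / (len(values) * bandwidth * math.sqrt(2 * math.pi))
    return grid, dens


def profile(
    assignments: AssignmentTable,
    group_id: str,
    member_subfamilies: list[str],
    species: str,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> DivergenceProfile:
    """Divergence profile of one family (or subfamily) in one species.

    Zero assigned copies yields an empty-profile sentinel (peak = NaN), which
    the extinction logic consumes; it is not an error.
    """
    t = assignments.table
    sel = t[(t.species == species) & (t.subfamily_id.isin(member_subfamilies))]
    values = sel.divergence_cpg_masked.to_numpy(dtype=float)
    total_bp = assignments.total_bp.get(species, 0)
    hist, _ = np.histogram(values, bins=np.arange(0.0, GRID_MAX + 1.0, 1.0))
    grid, dens = gaussian_kde_profile(values, bandwidth=bandwidth)
    if len(values) == 0:
        peak = math.nan
    else:
        peak = float(grid[int(np.argmax(dens))])  # argmax ties -> lowest divergence
    copies = float(len(values) * 3e9 / total_bp) if total_bp else math.nan
    return DivergenceProfile(
        group_id=group_id,
        species=species,
        histogram=hist,
        kde_grid=grid,
        kde=dens,
        peak=peak,
        raw_count=int(len(values)),
        copies_per_3gbp=copies,
    )


@dataclass
class EventReport:
    events: list[dict]  # one per family, oldest first
    coincident_pairs: list[tuple[str, str, float]]
    synchronized_families: list[tuple[str, float]]
    asymmetric_families: list[tuple[str, float]]
    extinction_calls: dict[str, dict[str, bool]]  # element -> species -> extinct?
    post_split_activity: dict[str, bool]
    split_estimate: float
    recency_threshold: float
    detection_floor: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=float)


def order_events(
    family_profiles: dict[str, dict[str, DivergenceProfile]],
    family_meta: dict[str, dict],
    split_estimate: float | None = None,
    coincidence_tol: float = 1.0,
    ratio_flag: float = 1.3,
    recency_offset: float = 2.0,
    detection_floor: dict | None = None,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> EventReport:
    """Order families in time and derive synchrony/asymmetry/extinction flags.

    ``family_profiles[family][species]`` are per-species profiles;
    ``family_meta[family]`` must carry ``element`` and ``species_presence``.
    If ``split_estimate`` is None it is derived as the oldest peak of any
    species-specific family plus one bandwidth (a detection-floor heuristic,
    flagged in the output).
    """
    if not family_profiles:
        raise ValueError("no family profiles")

    def present(fam: str, sp: str) -> bool:
        presence = family_meta[fam].get("species_presence")
        if presence is None:
            return not family_profiles[fam][sp].empty
        return sp in presence

    def peaks_of(fam: str) -> dict[str, float]:
        return {
            sp: p.peak
            for sp, p in family_profiles[fam].items()
            if not p.empty and present(fam, sp)
        }

    mean_peaks = {}
    for fam in family_profiles:
        pk = [v for v in peaks_of(fam).values() if not math.isnan(v)]
        mean_peaks[fam] = float(np.mean(pk)) if pk else math.nan

    derived_split = False
    if split_estimate is None:
        specific = [
            mean_peaks[f]
            for f in family_profiles
            if len(family_meta[f].get("species_presence", ())) == 1
            and not math.isnan(mean_peaks[f])
        ]
        split_estimate = (max(specific) + bandwidth) if specific else math.nan
        derived_split = True
    recency_threshold = split_estimate - recency_offset

    order = sorted(
        family_profiles,
        key=lambda f: (-(mean_peaks[f]) if not math.isnan(mean_peaks[f]) else math.inf, f),
    )
    events = []
    for fam in order:
        meta = family_meta[fam]
        events.append(
            dict(
                family=fam,
                element=meta.get("element", ""),
                presence_class=meta.get("presence_class", ""),
                species_presence=sorted(meta.get("species_presence", ())),
                peaks={sp: p.peak for sp, p in family_profiles[fam].items()},
                copies_per_3gbp={
                    sp: p.copies_per_3gbp for sp, p in family_profiles[fam].items()
                },
                mean_peak=mean_peaks[fam],
            )
        )

    synchronized = []
    asymmetric = []
    for fam in order:
        pk = peaks_of(fam)
        if len(pk) >= 2:
            vals = list(pk.values())
            if max(vals) - min(vals) <= coincidence_tol:
                synchronized.append((fam, float(max(vals) - min(vals))))
            copies = [
                family_profiles[fam][sp].copies_per_3gbp
                for sp in pk
                if family_profiles[fam][sp].raw_count > 0
            ]
            if len(copies) >= 2 and min(copies) > 0:
                ratio = max(copies) / min(copies)
                if ratio >= ratio_flag:
                    asymmetric.append((fam, float(ratio)))

    coincident = []
    for i, f1 in enumerate(order):
        for f2 in order[i + 1 :]:
            if math.isnan(mean_peaks[f1]) or math.isnan(mean_peaks[f2]):
                continue
            if abs(mean_peaks[f1] - mean_peaks[f2]) <= coincidence_tol:
                coincident.append((f1, f2, float(abs(mean_peaks[f1] - mean_peaks[f2]))))

    all_species = sorted({sp for fam in family_profiles for sp in family_profiles[fam]})
    elements = sorted({family_meta[f].get("element", "") for f in family_profiles})
    extinction: dict[str, dict[str, bool]] = {}
    post_split: dict[str, bool] = {sp: False for sp in all_species}
    for elem in elements:
        extinction[elem] = {}
        for sp in all_species:
            recent = False
            for fam in family_profiles:
                if family_meta[fam].get("element", "") != elem:
                    continue
                p = family_profiles[fam].get(sp)
                if p is None or p.empty:
                    continue
                if not present(fam, sp):
                    continue
                if not math.isnan(p.peak) and p.peak < recency_threshold:
                    recent = True
                if not math.isnan(p.peak) and p.peak < split_estimate:
                    post_split[sp] = True
            extinction[elem][sp] = not recent
    return EventReport(
        events=events,
        coincident_pairs=coincident,
        synchronized_families=synchronized,
        asymmetric_families=asymmetric,
        extinction_calls=extinction,
        post_split_activity=post_split,
        split_estimate=float(split_estimate),
        recency_threshold=float(recency_threshold),
        detection_floor=dict(
            detection_floor or {}, split_estimate_derived=derived_split
        ),
    )


def render_outputs(
    profiles: dict[str, dict[str, DivergenceProfile]],
    report: EventReport,
    outdir: str | Path,
    make_plots: bool = True,
) -> None:
    """Write events.tsv, report.json and the divergence-landscape figures.

    The TSV/JSON contents are deterministic given inputs; plots are rendered
    with the Agg backend (their bytes are not part of the contract).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for fam in sorted(profiles):
        for sp in sorted(profiles[fam]):
            p = profiles[fam][sp]
            rows.append(
                dict(
                    family=fam,
                    species=sp,
                    peak="NA" if math.isnan(p.peak) else round(p.peak, 2),
                    raw_copies=p.raw_count,
                    copies_per_3gbp="NA" if math.isnan(p.copies_per_3gbp) else round(p.copies_per_3gbp, 1),
                )
            )
    pd.DataFrame(rows).to_csv(outdir / "events.tsv", sep="\t", index=False)
    (outdir / "report.json").write_text(report.to_json() + "\n")
    if not make_plots:
        return

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 5))
    for fam in sorted(profiles):
        for sp in sorted(profiles[fam]):
            p = profiles[fam][sp]
            if p.empty:
                continue
            scale = p.copies_per_3gbp / max(p.kde.max(), 1e-12) if p.copies_per_3gbp else 1.0
            ax.plot(p.kde_grid, p.kde * scale, lw=1, label=f"{fam} ({sp})")
            ax.axvline(p.peak, ls="--", lw=0.6, color="grey")
    ax.set_xlabel("percent divergence from subfamily consensus (CpG-masked)")
    ax.set_ylabel("copies per 3 Gbp (KDE-scaled)")
    ax.set_xlim(0, min(GRID_MAX, 30))
    ax.legend(fontsize=5, ncol=2)
    fig.tight_layout()
    fig.savefig(outdir / "landscape_overlay.png", dpi=120)
    plt.close(fig)

    for fam in sorted(profiles):
        fig, axes = plt.subplots(
            1, max(1, len(profiles[fam])), figsize=(4 * max(1, len(profiles[fam])), 3), squeeze=False
        )
        for ax, sp in zip(axes[0], sorted(profiles[fam])):
            p = profiles[fam][sp]
            centers = np.arange(0.5, GRID_MAX, 1.0)
            weights = p.histogram * (p.copies_per_3gbp / p.raw_count if p.raw_count else 0.0)
            ax.bar(centers, weights, width=1.0)
            ax.set_title(f"{fam} {sp}", fontsize=8)
            ax.set_xlim(0, min(GRID_MAX, 30))
            ax.set_xlabel("% divergence")
        axes[0][0].set_ylabel("copies per 3 Gbp")
        fig.tight_layout()
        fig.savefig(outdir / f"family_{fam}.png", dpi=100)
        plt.close(fig)
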