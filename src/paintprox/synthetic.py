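"""Synthetic multiplexed localization data with known ground truth.

Emulates a sequential multiplexed DNA-PAINT ("exchange"/eraser-based)
experiment on the Golgi complex at the localization level: a parametric
layered Golgi model assigns every target protein a spatial support —
a cisternal rim at some offset along the cis→trans axis, punctate
contact sites at the interface between two cisternae, or a diffuse
distribution spanning the whole stack.  Labeled sites are drawn as a
Poisson process on the support; imaging of one target per round then
produces multiple stochastic localizations ("blinks") per site with
Gaussian localization error, a fixed antibody/nanobody linkage offset per
site, uniform false positives, a per-round rigid stage shift, and
carryover of a small fraction of the previous round's sites when erasure
of the previous adapter is incomplete.

The simulation starts at the localization level by design: there is no
camera, PSF or kinetic model.  Blinks are grouped into short runs of
consecutive frames to mimic binding events spanning a few camera frames,
which is what within-channel adjacent-frame precision estimators rely on.

Geometry
--------
The model is a set of ``n_stacks`` "ministacks" placed in the field of
view.  With ``curvature > 0`` each ministack is a closed ring (radius
``1/curvature``) — the en-face projection of a cisternal rim — and a layer
at axial offset ``o`` is the concentric ring of radius ``1/curvature + o``
(cis innermost).  With ``curvature == 0`` ministacks are straight segments
and layers are parallel segments displaced by ``o`` along ``stack_axis``;
this flat mode is the one with exactly parallel supports used by the
geometry-fidelity tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import LocalizationTable

__all__ = [
    "TargetLayout",
    "GolgiGeometry",
    "GolgiModel",
    "AcquisitionConfig",
    "GroundTruth",
    "ConfigurationError",
    "build_golgi_model",
    "sample_sites",
    "simulate_target_round",
    "simulate_experiment",
    "default_layouts",
    "default_geometry",
    "default_model",
    "default_acquisition",
]

NM_PER_UM2 = 1e-6  # converts densities given per µm² to per nm²


class ConfigurationError(ValueError):
    """Invalid model or acquisition parameters."""


@dataclass(frozen=True)
class TargetLayout:
    """Spatial distribution assigned to one target protein.

    ``distribution_kind`` is one of ``layer`` (cisternal rim at
    ``axial_offset`` nm along the cis→trans axis), ``interface_puncta``
    (``puncta_count`` disks of radius ``puncta_radius`` at the interface
    between the two layers named in ``between``, or at ``axial_offset``),
    or ``uniform_background`` (spread across the whole stack span).
    ``site_density`` is in labeled sites per µm² of support.
    """

    target_id: str
    distribution_kind: str = "layer"
    axial_offset: float = 0.0
    puncta_count: int = 0
    puncta_radius: float = 40.0
    site_density: float = 200.0
    between: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.distribution_kind not in ("layer", "interface_puncta", "uniform_background"):
            raise ConfigurationError(
                f"unknown distribution_kind '{self.distribution_kind}' for {self.target_id}"
            )
        if not math.isfinite(self.axial_offset):
            raise ConfigurationError(f"axial_offset must be finite for {self.target_id}")
        if self.site_density < 0:
            raise ConfigurationError(f"site_density must be >= 0 for {self.target_id}")
        if self.distribution_kind == "interface_puncta" and self.puncta_radius <= 0:
            raise ConfigurationError(f"puncta_radius must be > 0 for {self.target_id}")


@dataclass(frozen=True)
class GolgiGeometry:
    """Parametric stack geometry.

    ``ribbon_length`` is the total rim length (nm) split evenly across
    ``n_stacks`` ministacks; ``ribbon_width`` (nm) is the nominal labeled
    rim width used to convert areal site densities to linear ones;
    ``curvature`` (1/nm) bends each ministack into an arc or closed ring
    (0 = flat).  ``stack_axis`` is the in-plane cis→trans direction used by
    flat geometry.  ``field_of_view`` is (width, height) in nm.
    """

    ribbon_length: float = 22_000.0
    ribbon_width: float = 100.0
    curvature: float = 0.0
    stack_axis: tuple[float, float] = (0.0, 1.0)
    field_of_view: tuple[float, float] = (12_000.0, 12_000.0)
    n_stacks: int = 1

    def __post_init__(self) -> None:
        if self.ribbon_length <= 0 or self.ribbon_width <= 0:
            raise ConfigurationError("ribbon_length and ribbon_width must be > 0")
        if self.field_of_view[0] <= 0 or self.field_of_view[1] <= 0:
            raise ConfigurationError("field_of_view must be positive")
        if self.curvature < 0:
            raise ConfigurationError("curvature must be >= 0")
        if self.n_stacks < 1:
            raise ConfigurationError("n_stacks must be >= 1")
        norm = math.hypot(*self.stack_axis)
        if not math.isclose(norm, 1.0, rel_tol=1e-6):
            raise ConfigurationError("stack_axis must have unit norm")

    @property
    def stack_length(self) -> float:
        """Rim length of one ministack (nm)."""
        return self.ribbon_length / self.n_stacks


@dataclass(frozen=True)
class _Stack:
    """One realized ministack: a ring/arc (curvature > 0) or a segment."""

    center: tuple[float, float]
    angle: float  # arc start angle, or segment direction (flat)

    def layer_points(
        self, geom: GolgiGeometry, offset: float, arclens: np.ndarray
    ) -> np.ndarray:
        """Map arc-length positions on the layer at ``offset`` to xy (nm)."""
        cx, cy = self.center
        if geom.curvature > 0:
            r = 1.0 / geom.curvature + offset
            span = self._arc_span(geom)
            theta = self.angle + arclens / max(self.layer_length(geom, offset), 1e-12) * span
            return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
        ux, uy = math.cos(self.angle), math.sin(self.angle)
        nx, ny = geom.stack_axis
        t = arclens - geom.stack_length / 2.0
        return np.column_stack([cx + t * ux + offset * nx, cy + t * uy + offset * ny])

    def _arc_span(self, geom: GolgiGeometry) -> float:
        base_r = 1.0 / geom.curvature
        return min(2.0 * math.pi, geom.stack_length / base_r)

    def layer_length(self, geom: GolgiGeometry, offset: float) -> float:
        if geom.curvature > 0:
            r = 1.0 / geom.curvature + offset
            if r <= 0:
                return 0.0
            return self._arc_span(geom) * r
        return geom.stack_length


@dataclass(frozen=True)
class GolgiModel:
    """Realized layered Golgi: geometry, per-target layouts, stack placement."""

    geometry: GolgiGeometry
    layouts: tuple[TargetLayout, ...]
    seed: int
    stacks: tuple[_Stack, ...] = ()
    puncta_centers: Mapping[str, np.ndarray] = field(default_factory=dict)

    @property
    def target_ids(self) -> list[str]:
        return [lay.target_id for lay in self.layouts]

    def layout(self, target_id: str) -> TargetLayout:
        for lay in self.layouts:
            if lay.target_id == target_id:
                return lay
        raise KeyError(f"unknown target '{target_id}' (model has {self.target_ids})")

    def resolved_offset(self, layout: TargetLayout) -> float:
        """Axial position of a layout, resolving ``between`` pairs."""
        if layout.distribution_kind == "interface_puncta" and layout.between is not None:
            a = self.layout(layout.between[0]).axial_offset
            b = self.layout(layout.between[1]).axial_offset
            return 0.5 * (a + b)
        return layout.axial_offset

    def axial_span(self) -> tuple[float, float]:
        offs = [self.resolved_offset(lay) for lay in self.layouts]
        return (min(offs), max(offs))

    def support_distance(self, target_a: str, target_b: str) -> float:
        """Analytic minimum distance between two targets' supports (nm)."""
        la, lb = self.layout(target_a), self.layout(target_b)
        oa, ob = self.resolved_offset(la), self.resolved_offset(lb)
        gap = abs(oa - ob)
        if la.distribution_kind == "interface_puncta":
            gap = max(0.0, gap - la.puncta_radius)
        if lb.distribution_kind == "interface_puncta":
            gap = max(0.0, gap - lb.puncta_radius)
        if "uniform_background" in (la.distribution_kind, lb.distribution_kind):
            lo, hi = self.axial_span()
            gap = 0.0  # the diffuse support overlaps every layer
        return gap


def build_golgi_model(
    geometry: GolgiGeometry, layouts: Sequence[TargetLayout], seed: int
) -> GolgiModel:
    """Place ministacks and puncta; fully deterministic given ``seed``."""
    layouts = tuple(layouts)
    if not layouts:
        raise ConfigurationError("at least one target layout is required")
    ids = [lay.target_id for lay in layouts]
    if len(set(ids)) != len(ids):
        dupes = sorted({t for t in ids if ids.count(t) > 1})
        raise ConfigurationError(f"duplicate target_id(s): {dupes}")
    for lay in layouts:
        if lay.between is not None:
            for name in lay.between:
                if name not in ids:
                    raise ConfigurationError(
                        f"{lay.target_id}.between names unknown target '{name}'"
                    )

    rng = np.random.default_rng(seed)
    fw, fh = geometry.field_of_view
    n = geometry.n_stacks
    if n == 1:
        centers = np.array([[fw / 2.0, fh / 2.0]])
    else:
        # ministacks on a ring around the FOV center, with seeded jitter
        ring_r = 0.30 * min(fw, fh)
        phases = 2.0 * math.pi * (np.arange(n) / n) + rng.uniform(0, 2 * math.pi)
        jitter = rng.uniform(-0.05, 0.05, size=(n, 2)) * min(fw, fh)
        centers = np.column_stack(
            [fw / 2.0 + ring_r * np.cos(phases), fh / 2.0 + ring_r * np.sin(phases)]
        ) + jitter
    if geometry.curvature > 0:
        angles = rng.uniform(0, 2 * math.pi, size=n)  # arc start angles
    else:
        # flat ribbons run perpendicular to the (global) cis→trans axis so
        # that layer offsets displace them along stack_axis
        angles = np.full(n, math.atan2(geometry.stack_axis[1], geometry.stack_axis[0]) + math.pi / 2.0)
    stacks = tuple(_Stack((float(c[0]), float(c[1])), float(a)) for c, a in zip(centers, angles))

    model = GolgiModel(geometry=geometry, layouts=layouts, seed=seed, stacks=stacks)
    puncta: dict[str, np.ndarray] = {}
    for lay in layouts:
        if lay.distribution_kind != "interface_puncta":
            continue
        offset = model.resolved_offset(lay)
        count = int(lay.puncta_count)
        # spread puncta across ministacks, at seeded positions on the interface
        stack_idx = np.arange(count) % n
        pts = []
        for k in range(count):
            st = stacks[int(stack_idx[k])]
            length = st.layer_length(geometry, offset)
            s = rng.uniform(0, length)
            pts.append(st.layer_points(geometry, offset, np.array([s]))[0])
        puncta[lay.target_id] = np.asarray(pts) if pts else np.empty((0, 2))
    return replace(model, puncta_centers=puncta)


def sample_sites(model: GolgiModel, target_id: str, seed: int) -> np.ndarray:
    """Draw labeled-site coordinates for one target.

    Sites form a homogeneous Poisson process on the target's support:
    expected count = ``site_density`` × support area, where a layer's area
    is its rim length × ``ribbon_width`` and a punctum's is π r².
    Returns an (n, 2) array in nm.
    """
    layout = model.layout(target_id)
    rng = np.random.default_rng(seed)
    geom = model.geometry
    density_nm2 = layout.site_density * NM_PER_UM2
    if layout.distribution_kind == "layer":
        offset = layout.axial_offset
        lam_lin = density_nm2 * geom.ribbon_width  # sites per nm of rim
        pts = []
        for st in model.stacks:
            length = st.layer_length(geom, offset)
            count = rng.poisson(lam_lin * length)
            if count:
                s = rng.uniform(0, length, size=count)
                pts.append(st.layer_points(geom, offset, s))
        return np.concatenate(pts) if pts else np.empty((0, 2))
    if layout.distribution_kind == "interface_puncta":
        centers = np.asarray(model.puncta_centers.get(target_id, np.empty((0, 2))))
        area = math.pi * layout.puncta_radius**2
        pts = []
        for c in centers:
            count = rng.poisson(density_nm2 * area)
            if count:
                r = layout.puncta_radius * np.sqrt(rng.uniform(0, 1, size=count))
                th = rng.uniform(0, 2 * math.pi, size=count)
                pts.append(np.column_stack([c[0] + r * np.cos(th), c[1] + r * np.sin(th)]))
        return np.concatenate(pts) if pts else np.empty((0, 2))
    # uniform_background: band spanning all layers of the stack
    lo, hi = model.axial_span()
    lo -= geom.ribbon_width / 2.0
    hi += geom.ribbon_width / 2.0
    pts = []
    for st in model.stacks:
        if geom.curvature > 0:
            base_r = 1.0 / geom.curvature
            r_in, r_out = max(0.0, base_r + lo), base_r + hi
            span = st._arc_span(geom)
            area = 0.5 * span * (r_out**2 - r_in**2)
            count = rng.poisson(density_nm2 * area)
            if count:
                u = rng.uniform(r_in**2, r_out**2, size=count)
                rr = np.sqrt(u)
                th = st.angle + rng.uniform(0, span, size=count)
                cx, cy = st.center
                pts.append(np.column_stack([cx + rr * np.cos(th), cy + rr * np.sin(th)]))
        else:
            area = geom.stack_length * (hi - lo)
            count = rng.poisson(density_nm2 * area)
            if count:
                s = rng.uniform(0, geom.stack_length, size=count)
                o = rng.uniform(lo, hi, size=count)
                ux, uy = math.cos(st.angle), math.sin(st.angle)
                nx, ny = geom.stack_axis
                cx, cy = st.center
                t = s - geom.stack_length / 2.0
                pts.append(
                    np.column_stack([cx + t * ux + o * nx, cy + t * uy + o * ny])
                )
    return np.concatenate(pts) if pts else np.empty((0, 2))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Per-round stochastic imaging parameters.

    ``mean_blinks_per_site`` controls how many localizations each labeled
    site yields per round under ``blink_count_law`` (``poisson``,
    ``geometric``, or ``fixed`` for an exact count).  ``sigma_loc`` is the
    per-coordinate Gaussian localization error per blink (nm);
    ``linkage_radius`` the fixed-magnitude, random-direction label offset
    drawn once per site (nm).  ``false_rate`` is false localizations per
    µm² per round; ``erasure_efficiency`` the fraction of the previous
    round's sites successfully silenced; ``round_shifts`` the per-round
    rigid stage offsets in nm.  Blinks are grouped into binding events
    spanning on average ``mean_event_frames`` consecutive camera frames out
    of ``frames_per_round``.
    """

    round_order: tuple[str, ...]
    mean_blinks_per_site: float = 4.0
    blink_count_law: str = "poisson"
    sigma_loc: float = 5.0
    linkage_radius: float = 7.0
    false_rate: float = 1.0
    erasure_efficiency: float = 0.995
    round_shifts: tuple[tuple[float, float], ...] | None = None
    pixel_size: float = 108.0
    frames_per_round: int = 30_000
    mean_event_frames: float = 3.0

    def __post_init__(self) -> None:
        if not self.round_order:
            raise ConfigurationError("round_order must name at least one target")
        if self.mean_blinks_per_site < 0:
            raise ConfigurationError("mean_blinks_per_site must be >= 0")
        if self.blink_count_law not in ("poisson", "geometric", "fixed"):
            raise ConfigurationError(f"unknown blink_count_law '{self.blink_count_law}'")
        if self.sigma_loc < 0 or self.linkage_radius < 0 or self.false_rate < 0:
            raise ConfigurationError("sigma_loc, linkage_radius, false_rate must be >= 0")
        if not 0.0 <= self.erasure_efficiency <= 1.0:
            raise ConfigurationError("erasure_efficiency must lie in [0, 1]")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")
        if self.round_shifts is not None and len(self.round_shifts) != len(self.round_order):
            raise ConfigurationError("round_shifts must have one (dx, dy) per round")
        if self.frames_per_round < 1 or self.mean_event_frames < 1:
            raise ConfigurationError("frames_per_round and mean_event_frames must be >= 1")

    def shift_for(self, round_index: int) -> tuple[float, float]:
        if self.round_shifts is None:
            return (0.0, 0.0)
        return tuple(self.round_shifts[round_index])  # type: ignore[return-value]


@dataclass(frozen=True)
class GroundTruth:
    """Everything the simulator knows that an experimenter would not."""

    sites: Mapping[str, np.ndarray]
    shifts: Mapping[str, tuple[float, float]]
    support_distances: pd.DataFrame  # long form: target_a, target_b, distance_nm


def _blink_counts(rng: np.random.Generator, law: str, mean: float, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if law == "poisson":
        return rng.poisson(mean, size=n).astype(np.int64)
    if law == "geometric":
        # support 0, 1, 2, ... with the requested mean
        p = 1.0 / (1.0 + mean)
        return (rng.geometric(p, size=n) - 1).astype(np.int64)
    return np.full(n, int(round(mean)), dtype=np.int64)


def _event_frames(
    rng: np.random.Generator, counts: np.ndarray, n_frames: int, mean_event: float
) -> np.ndarray:
    """Assign each blink a frame; blinks of a site form consecutive runs."""
    frames = np.empty(int(counts.sum()), dtype=np.int64)
    pos = 0
    p = 1.0 / mean_event
    for k in counts:
        remaining = int(k)
        while remaining > 0:
            length = min(int(rng.geometric(p)), remaining)
            start = int(rng.integers(0, max(1, n_frames - length)))
            frames[pos : pos + length] = np.arange(start, start + length)
            pos += length
            remaining -= length
    return frames


def _emit_blinks(
    rng: np.random.Generator,
    sites: np.ndarray,
    cfg: AcquisitionConfig,
    flag: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Blinks for a set of sites: returns (xy, frames, flags)."""
    n = len(sites)
    counts = _blink_counts(rng, cfg.blink_count_law, cfg.mean_blinks_per_site, n)
    # one rigid label offset per site, fixed for the round
    ang = rng.uniform(0, 2 * math.pi, size=n)
    anchors = sites + cfg.linkage_radius * np.column_stack([np.cos(ang), np.sin(ang)])
    xy = np.repeat(anchors, counts, axis=0)
    if cfg.sigma_loc > 0 and len(xy):
        xy = xy + rng.normal(0.0, cfg.sigma_loc, size=xy.shape)
    frames = _event_frames(rng, counts, cfg.frames_per_round, cfg.mean_event_frames)
    flags = np.full(len(xy), flag, dtype=object)
    return xy, frames, flags


def simulate_target_round(
    sites: np.ndarray,
    cfg: AcquisitionConfig,
    round_index: int,
    previous_round_sites: np.ndarray | None = None,
    seed: int = 0,
    field_of_view: tuple[float, float] = (12_000.0, 12_000.0),
    channel: str | None = None,
) -> LocalizationTable:
    """Simulate one imaging round for one target.

    Produces blinks from the round's own sites, carryover blinks from a
    fraction ``1 - erasure_efficiency`` of the previous round's sites, and
    uniform false positives, all displaced by the round's rigid shift.
    """
    if not 0 <= round_index < len(cfg.round_order):
        raise ConfigurationError(
            f"round_index {round_index} outside round_order of {len(cfg.round_order)}"
        )
    rng = np.random.default_rng(seed)
    sites = np.asarray(sites, float).reshape(-1, 2)

    xy, frames, flags = _emit_blinks(rng, sites, cfg, "true_site")
    parts_xy, parts_fr, parts_fl = [xy], [frames], [flags]

    if previous_round_sites is not None and len(previous_round_sites):
        prev = np.asarray(previous_round_sites, float).reshape(-1, 2)
        survived = rng.uniform(size=len(prev)) < (1.0 - cfg.erasure_efficiency)
        cxy, cfr, _ = _emit_blinks(rng, prev[survived], cfg, "carryover")
        parts_xy.append(cxy)
        parts_fr.append(cfr)
        parts_fl.append(np.full(len(cxy), "carryover", dtype=object))

    fw, fh = field_of_view
    n_false = rng.poisson(cfg.false_rate * NM_PER_UM2 * fw * fh)
    if n_false:
        fxy = np.column_stack(
            [rng.uniform(0, fw, size=n_false), rng.uniform(0, fh, size=n_false)]
        )
        parts_xy.append(fxy)
        parts_fr.append(rng.integers(0, cfg.frames_per_round, size=n_false))
        parts_fl.append(np.full(n_false, "false_positive", dtype=object))

    xy = np.concatenate(parts_xy)
    frames = np.concatenate(parts_fr)
    flags = np.concatenate(parts_fl)
    dx, dy = cfg.shift_for(round_index)
    data = pd.DataFrame(
        {
            "x_nm": xy[:, 0] + dx,
            "y_nm": xy[:, 1] + dy,
            "frame": frames.astype(np.int64),
            "precision_nm": np.full(len(xy), float(cfg.sigma_loc)),
            "origin_flag": flags,
        }
    )
    name = channel if channel is not None else cfg.round_order[round_index]
    return LocalizationTable(data, channel=name, round_index=round_index)


def simulate_experiment(
    model: GolgiModel, cfg: AcquisitionConfig, seed: int
) -> tuple[dict[str, LocalizationTable], GroundTruth]:
    """Run the full sequential acquisition: one round per target in order.

    Carryover chains round ``i`` into round ``i + 1`` only.  Fully
    reproducible from ``seed``.
    """
    unknown = [t for t in cfg.round_order if t not in model.target_ids]
    if unknown:
        raise ConfigurationError(f"round_order names targets absent from model: {unknown}")
    ss = np.random.SeedSequence(seed)
    site_seeds, round_seeds = ss.spawn(2)
    site_children = site_seeds.spawn(len(cfg.round_order))
    round_children = round_seeds.spawn(len(cfg.round_order))

    sites = {
        t: sample_sites(model, t, int(child.generate_state(1)[0] % 2**31))
        for t, child in zip(cfg.round_order, site_children)
    }
    tables: dict[str, LocalizationTable] = {}
    shifts: dict[str, tuple[float, float]] = {}
    prev: np.ndarray | None = None
    for i, target in enumerate(cfg.round_order):
        tables[target] = simulate_target_round(
            sites[target],
            cfg,
            round_index=i,
            previous_round_sites=prev,
            seed=int(round_children[i].generate_state(1)[0] % 2**31),
            field_of_view=model.geometry.field_of_view,
            channel=target,
        )
        shifts[target] = cfg.shift_for(i)
        prev = sites[target]

    rows = []
    for a in cfg.round_order:
        for b in cfg.round_order:
            if a != b:
                rows.append((a, b, model.support_distance(a, b)))
    truth = GroundTruth(
        sites=sites,
        shifts=shifts,
        support_distances=pd.DataFrame(
            rows, columns=["target_a", "target_b", "distance_nm"]
        ),
    )
    return tables, truth


# --------------------------------------------------------------------------
# Default study-emulating model: a layered Golgi with cis→trans markers and
# VPS13B confined to puncta at the cis/medial interface.

#: cis→trans axial offsets (nm) of the reference markers.  GM130/GRASP65 mark
#: the cis face, Giantin/GALNT2/Rab6 medial cisternae, Golgin97/TGN46 the TGN.
DEFAULT_LAYER_OFFSETS: dict[str, float] = {
    "GRASP65": -5.0,
    "GM130": 0.0,
    "Giantin": 65.0,
    "GALNT2": 73.0,
    "Rab6": 81.0,
    "Golgin97": 100.0,
    "TGN46": 110.0,
}

#: axial position of the VPS13B contact-site puncta: anchored 28 nm from
#: GM130 on the cis side of the cis/medial gap, reproducing the observed
#: marker distances (closest to GM130, then GRASP65), rather than at the
#: geometric midpoint of the gap
DEFAULT_VPS13B_OFFSET = 28.0

#: the default acquisition images VPS13B plus the seven reference markers;
#: the diffuse FAM177A1 channel is part of the default model and can be
#: appended to the round order to emulate the nine-target experiment
DEFAULT_ROUND_ORDER: tuple[str, ...] = (
    "GM130",
    "GRASP65",
    "VPS13B",
    "Giantin",
    "GALNT2",
    "Rab6",
    "Golgin97",
    "TGN46",
)


def default_layouts() -> list[TargetLayout]:
    """Layouts emulating the multiplexed Golgi experiment."""
    layouts = [
        TargetLayout(name, "layer", axial_offset=off, site_density=200.0)
        for name, off in DEFAULT_LAYER_OFFSETS.items()
    ]
    layouts.append(
        TargetLayout(
            "VPS13B",
            "interface_puncta",
            axial_offset=DEFAULT_VPS13B_OFFSET,
            puncta_count=160,  # 20 contact-site puncta per ministack
            puncta_radius=40.0,
            site_density=4000.0,
        )
    )
    layouts.append(
        TargetLayout("FAM177A1", "uniform_background", site_density=200.0)
    )
    return layouts


def default_geometry() -> GolgiGeometry:
    """Eight ring-shaped ministacks (rim radius 450 nm) in a 12 µm field."""
    n_stacks = 8
    radius = 450.0
    return GolgiGeometry(
        ribbon_length=n_stacks * 2.0 * math.pi * radius,
        ribbon_width=200.0,
        curvature=1.0 / radius,
        field_of_view=(12_000.0, 12_000.0),
        n_stacks=n_stacks,
    )


def default_model(seed: int = 0) -> GolgiModel:
    return build_golgi_model(default_geometry(), default_layouts(), seed)


def default_acquisition(
    round_shifts: Sequence[tuple[float, float]] | None = None,
) -> AcquisitionConfig:
    return AcquisitionConfig(
        round_order=DEFAULT_ROUND_ORDER,
        round_shifts=tuple(map(tuple, round_shifts)) if round_shifts is not None else None,
    )
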