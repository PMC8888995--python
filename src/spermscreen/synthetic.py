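"""Synthetic sperm-motility data with known ground truth.

Every downstream stage (tracking, kinematics, normalization, hit
calling, dose-response fitting) is exercised against data produced
here, so the generator records the truth it used: per-detection track
ids, per-track motility class, and per-compound effect parameters.

The motion model is a persistent random walk in 2-D: per frame a cell
takes a step whose speed is drawn from a class-specific normal
distribution (truncated at zero) and whose heading evolves by
wrapped-normal increments.  The per-step heading correlation
``E[cos(dtheta)] = exp(-sigma^2/2)`` is the class's
``directional_persistence``: progressively motile cells are nearly
ballistic (persistence near 1), non-progressive cells turn erratically
(low persistence), immotile cells do not step at all and only jitter by
localization noise.  No flagellar mechanics, 3-D motion, or
capacitation dynamics are modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import DoseSeries, dilution_series
from .tracking import Track

__all__ = [
    "DEFAULT_CLASS_PARAMS",
    "CompoundEffectModel",
    "MotilityClassParams",
    "PlateSimConfig",
    "PlateSimulation",
    "PopulationConfig",
    "SimulatedField",
    "render_frames",
    "simulate_dose_response",
    "simulate_field",
    "simulate_plate",
    "simulate_track",
    "true_percent_of_control",
    "well_names",
]

CLASS_LABELS = ("IM", "NPM", "PM")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _finite(*values: float) -> bool:
    return all(np.isfinite(v) for v in values)


@dataclass(frozen=True)
class MotilityClassParams:
    """Motion parameters of one motility class (IM, NPM or PM).

    speed_mean / speed_sd are the per-step speed distribution in um/s;
    directional_persistence in [0, 1] is the per-step heading
    correlation; positional_noise_sd (um) is isotropic localization
    noise added to every observed position.
    """

    class_label: str
    speed_mean: float
    speed_sd: float
    directional_persistence: float
    positional_noise_sd: float

    def __post_init__(self) -> None:
        _require(self.class_label in CLASS_LABELS, f"unknown class {self.class_label!r}")
        _require(
            _finite(
                self.speed_mean,
                self.speed_sd,
                self.directional_persistence,
                self.positional_noise_sd,
            ),
            "motility-class parameters must be finite",
        )
        _require(self.speed_mean >= 0, "speed_mean must be >= 0")
        _require(self.speed_sd >= 0, "speed_sd must be >= 0")
        _require(0.0 <= self.directional_persistence <= 1.0, "persistence must be in [0, 1]")
        _require(self.positional_noise_sd >= 0, "positional_noise_sd must be >= 0")


#: Default motility classes for density-gradient-prepared donor sperm.
#: Speeds are in the range CASA reports for human sperm imaged at body
#: temperature; the immotile class moves by localization jitter only.
DEFAULT_CLASS_PARAMS: Mapping[str, MotilityClassParams] = {
    "IM": MotilityClassParams("IM", 0.0, 0.0, 0.0, 0.2),
    "NPM": MotilityClassParams("NPM", 35.0, 12.0, 0.3, 0.5),
    "PM": MotilityClassParams("PM", 90.0, 20.0, 0.98, 0.5),
}


@dataclass(frozen=True)
class PopulationConfig:
    """One imaged field of view's cell population.

    class_fractions are (IM, NPM, PM) and must sum to 1.  Defaults are
    desk-scale: 500 cells per field rather than the ~10,000 per well of
    the full-scale assay, 25 frames/s for 2 s.
    """

    n_cells: int = 500
    class_fractions: tuple[float, float, float] = (0.2, 0.2, 0.6)
    frame_rate: float = 25.0
    n_frames: int = 50
    field_size: tuple[float, float] = (1300.0, 1000.0)
    detection_dropout_prob: float = 0.0
    placement: str = "uniform"  # or "grid" (jittered square lattice)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cells >= 1, "n_cells must be >= 1")
        _require(len(self.class_fractions) == 3, "class_fractions must have 3 entries")
        _require(
            abs(sum(self.class_fractions) - 1.0) <= 1e-9,
            "class_fractions must sum to 1",
        )
        _require(all(f >= 0 for f in self.class_fractions), "fractions must be >= 0")
        _require(self.n_frames >= 2, "n_frames must be >= 2")
        _require(_finite(self.frame_rate) and self.frame_rate > 0, "frame_rate must be > 0")
        _require(
            all(_finite(s) and s > 0 for s in self.field_size),
            "field_size must be positive",
        )
        _require(0.0 <= self.detection_dropout_prob <= 1.0, "dropout must be in [0, 1]")
        _require(self.placement in ("uniform", "grid"), "placement must be uniform|grid")


@dataclass(frozen=True)
class CompoundEffectModel:
    """Ground-truth dose-dependent motility enhancement of one compound.

    The activation at concentration c follows the same four-parameter
    logistic shape the fitter assumes, h(c) = 1 / (1 + (ec50/c)^hill),
    h(0) = 0.  It scales motile-class speeds by
    1 + (max_speed_multiplier - 1) * h and shifts up to
    max_pm_fraction_shift of the population into the PM class.
    """

    ec50_true: float = 0.5
    hill_true: float = 1.0
    max_speed_multiplier: float = 1.5
    max_pm_fraction_shift: float = 0.0

    def __post_init__(self) -> None:
        _require(_finite(self.ec50_true) and self.ec50_true > 0, "ec50_true must be > 0")
        _require(_finite(self.hill_true) and self.hill_true > 0, "hill_true must be > 0")
        _require(self.max_speed_multiplier >= 1.0, "multiplier must be >= 1 (enhancer)")
        _require(0.0 <= self.max_pm_fraction_shift <= 1.0, "pm shift must be in [0, 1]")

    def activation(self, concentration_uM: float | np.ndarray) -> float | np.ndarray:
        """Fractional activation h(c) in [0, 1); exactly 0 at c = 0."""
        c = np.asarray(concentration_uM, dtype=float)
        with np.errstate(divide="ignore"):
            h = np.where(c > 0, 1.0 / (1.0 + (self.ec50_true / np.where(c > 0, c, 1.0)) ** self.hill_true), 0.0)
        return float(h) if np.isscalar(concentration_uM) else h

    def speed_multiplier(self, concentration_uM: float) -> float:
        return 1.0 + (self.max_speed_multiplier - 1.0) * float(self.activation(concentration_uM))


NULL_EFFECT = CompoundEffectModel(max_speed_multiplier=1.0, max_pm_fraction_shift=0.0)


def true_percent_of_control(effect: CompoundEffectModel, concentration_uM: float | np.ndarray):
    """Expected % of control at a concentration under the effect model.

    The well statistic is the median track VCL; scaling all motile-class
    speeds by m scales that median by m whenever it falls inside the
    motile part of the VCL distribution, so the expected normalized
    value is 100 * m(c).
    """
    c = np.asarray(concentration_uM, dtype=float)
    m = 1.0 + (effect.max_speed_multiplier - 1.0) * effect.activation(c)
    out = 100.0 * m
    return float(out) if np.isscalar(concentration_uM) else out


# ---------------------------------------------------------------------------
# track / field simulation


def _heading_sigma(persistence: float) -> float | None:
    """Wrapped-normal turn SD giving E[cos(dtheta)] = persistence.

    Returns None for persistence 0, meaning headings are redrawn
    uniformly every step (no correlation at all).
    """
    if persistence <= 0.0:
        return None
    if persistence >= 1.0:
        return 0.0
    return math.sqrt(-2.0 * math.log(persistence))


def _simulate_class_tracks(
    params: MotilityClassParams,
    n_tracks: int,
    n_frames: int,
    frame_rate: float,
    starts: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized persistent random walk; returns (n_tracks, n_frames, 2) um."""
    n_steps = n_frames - 1
    if params.speed_mean == 0.0 and params.speed_sd == 0.0:
        steps = np.zeros((n_tracks, n_steps, 2))
    else:
        speeds = rng.normal(params.speed_mean, params.speed_sd, size=(n_tracks, n_steps))
        np.clip(speeds, 0.0, None, out=speeds)
        theta0 = rng.uniform(0.0, 2.0 * math.pi, size=(n_tracks, 1))
        sigma = _heading_sigma(params.directional_persistence)
        if n_steps > 1:
            if sigma is None:
                dtheta = rng.uniform(-math.pi, math.pi, size=(n_tracks, n_steps - 1))
            else:
                dtheta = rng.normal(0.0, sigma, size=(n_tracks, n_steps - 1))
            theta = theta0 + np.concatenate(
                [np.zeros((n_tracks, 1)), np.cumsum(dtheta, axis=1)], axis=1
            )
        else:
            theta = np.broadcast_to(theta0, (n_tracks, 1))
        lengths = speeds / frame_rate
        steps = np.stack([lengths * np.cos(theta), lengths * np.sin(theta)], axis=2)
    pos = np.concatenate([np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    pos += starts[:, None, :]
    if params.positional_noise_sd > 0:
        pos = pos + rng.normal(0.0, params.positional_noise_sd, size=pos.shape)
    return pos


def simulate_track(
    params: MotilityClassParams,
    n_frames: int,
    frame_rate: float,
    seed: int | None = None,
    start: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> Track:
    """Simulate one track of the given motility class.

    Reproducible: the same params/seed give bit-identical output.
    """
    _require(n_frames >= 2, "n_frames must be >= 2")
    _require(_finite(frame_rate) and frame_rate > 0, "frame_rate must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    pos = _simulate_class_tracks(params, 1, n_frames, frame_rate, np.array([start], float), rng)
    return Track(
        track_id=0,
        frames=np.arange(n_frames),
        x=pos[0, :, 0].copy(),
        y=pos[0, :, 1].copy(),
    )


@dataclass
class SimulatedField:
    """One simulated field of view.

    ``detections`` is what the instrument would report (frame, x_um,
    y_um); ``truth_track_id`` is the aligned ground-truth id side
    channel; ``truth`` is the full pre-dropout track table with class
    labels; ``track_classes`` maps track_id -> class label.
    """

    detections: pd.DataFrame
    truth_track_id: np.ndarray
    truth: pd.DataFrame
    track_classes: pd.Series
    config: PopulationConfig

    def truth_sidecar(self) -> pd.DataFrame:
        """Ground-truth ids aligned with ``detections`` rows, as a table."""
        return pd.DataFrame(
            {"detection_index": np.arange(len(self.detections)), "track_id": self.truth_track_id}
        )


def _start_positions(cfg: PopulationConfig, rng: np.random.Generator) -> np.ndarray:
    w, h = cfg.field_size
    if cfg.placement == "uniform":
        return rng.uniform([0.0, 0.0], [w, h], size=(cfg.n_cells, 2))
    # jittered square lattice, jitter 10% of pitch
    n_side = int(math.ceil(math.sqrt(cfg.n_cells)))
    px, py = w / n_side, h / n_side
    gx, gy = np.meshgrid(np.arange(n_side), np.arange(n_side))
    pts = np.column_stack([(gx.ravel() + 0.5) * px, (gy.ravel() + 0.5) * py])[: cfg.n_cells]
    return pts + rng.normal(0.0, 0.1 * min(px, py), size=pts.shape)


def simulate_field(
    pop: PopulationConfig,
    class_params: Mapping[str, MotilityClassParams] | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedField:
    """Simulate one field: a mixture of IM/NPM/PM tracks plus dropout.

    Class counts are a single multinomial draw from
    ``pop.class_fractions``; each detection is then independently
    removed with probability ``pop.detection_dropout_prob``.
    """
    if class_params is None:
        class_params = DEFAULT_CLASS_PARAMS
    if rng is None:
        rng = np.random.default_rng(pop.seed)
    counts = rng.multinomial(pop.n_cells, np.asarray(pop.class_fractions, float))
    starts = _start_positions(pop, rng)
    n, F = pop.n_cells, pop.n_frames

    positions = np.empty((n, F, 2))
    labels = np.empty(n, dtype=object)
    i0 = 0
    for label, count in zip(CLASS_LABELS, counts):
        if count == 0:
            continue
        positions[i0 : i0 + count] = _simulate_class_tracks(
            class_params[label], count, F, pop.frame_rate, starts[i0 : i0 + count], rng
        )
        labels[i0 : i0 + count] = label
        i0 += count

    track_ids = np.repeat(np.arange(n), F)
    frames = np.tile(np.arange(F), n)
    truth = pd.DataFrame(
        {
            "track_id": track_ids,
            "frame": frames,
            "x_um": positions[:, :, 0].ravel(),
            "y_um": positions[:, :, 1].ravel(),
            "class_label": np.repeat(labels, F),
        }
    )
    # detections sorted by frame (acquisition order)
    order = np.lexsort((track_ids, frames))
    keep = np.ones(n * F, dtype=bool)
    if pop.detection_dropout_prob > 0:
        keep = rng.random(n * F) >= pop.detection_dropout_prob
    kept = order[keep[order]]
    detections = pd.DataFrame(
        {
            "frame": frames[kept],
            "x_um": positions[:, :, 0].ravel()[kept],
            "y_um": positions[:, :, 1].ravel()[kept],
        }
    ).reset_index(drop=True)
    return SimulatedField(
        detections=detections,
        truth_track_id=track_ids[kept].copy(),
        truth=truth,
        track_classes=pd.Series(labels, index=np.arange(n), name="class_label"),
        config=pop,
    )


# ---------------------------------------------------------------------------
# plates


def well_names(n_rows: int = 16, n_cols: int = 24) -> list[str]:
    """A01..P24 well names of a 384-well plate, row-major."""
    return [f"{chr(ord('A') + r)}{c + 1:02d}" for r in range(n_rows) for c in range(n_cols)]


@dataclass(frozen=True)
class PlateSimConfig:
    """One simulated 384-well screening plate.

    Vehicle-control (DMSO) wells share the untreated null population;
    compound wells apply their effect model at ``screen_concentration``
    (single-concentration primary screen).  Compounds are allocated to
    wells at random.
    """

    n_control_wells: int = 16
    n_compound_wells: int = 368
    screen_concentration_uM: float = 6.25
    effects: Mapping[str, CompoundEffectModel] = field(default_factory=dict)
    compound_ids: Sequence[str] | None = None
    library_id: str = "SIMLIB"
    population: PopulationConfig = field(default_factory=PopulationConfig)
    n_fields_per_well: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_control_wells >= 1, "need at least one control well")
        _require(self.n_compound_wells >= 0, "n_compound_wells must be >= 0")
        _require(
            self.n_control_wells + self.n_compound_wells <= 384,
            "a 384-well plate holds at most 384 wells",
        )
        _require(self.screen_concentration_uM > 0, "screen concentration must be > 0")
        _require(self.n_fields_per_well >= 1, "need at least one field per well")
        if self.compound_ids is not None:
            _require(
                len(self.compound_ids) == self.n_compound_wells,
                "compound_ids length must equal n_compound_wells",
            )


def _effective_population(
    class_params: Mapping[str, MotilityClassParams],
    fractions: tuple[float, float, float],
    effect: CompoundEffectModel,
    concentration_uM: float,
) -> tuple[Mapping[str, MotilityClassParams], tuple[float, float, float]]:
    """Apply a compound effect: scale motile speeds, shift NPM/IM into PM."""
    h = float(effect.activation(concentration_uM))
    if h == 0.0:
        return class_params, fractions
    m = 1.0 + (effect.max_speed_multiplier - 1.0) * h
    scaled = dict(class_params)
    for label in ("NPM", "PM"):
        p = class_params[label]
        scaled[label] = replace(p, speed_mean=p.speed_mean * m, speed_sd=p.speed_sd * m)
    im, npm, pm = fractions
    shift = effect.max_pm_fraction_shift * h
    from_npm = min(shift, npm)
    from_im = min(shift - from_npm, im)
    fractions = (im - from_im, npm - from_npm, pm + from_npm + from_im)
    return scaled, fractions


class PlateSimulation:
    """Lazy per-well field generator for one simulated plate.

    Fields are generated on demand from seeds derived deterministically
    from (plate seed, well index, field index), so a plate never needs
    to be materialized in memory at once and any single well can be
    regenerated bit-identically.
    """

    def __init__(
        self,
        config: PlateSimConfig,
        class_params: Mapping[str, MotilityClassParams] | None = None,
    ):
        self.config = config
        self.class_params = dict(class_params or DEFAULT_CLASS_PARAMS)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 384]))
        names = well_names()
        order = rng.permutation(len(names))
        n_ctrl, n_cpd = config.n_control_wells, config.n_compound_wells
        control_wells = [names[i] for i in sorted(order[:n_ctrl])]
        compound_wells = [names[i] for i in sorted(order[n_ctrl : n_ctrl + n_cpd])]
        if config.compound_ids is not None:
            cpd_ids = list(config.compound_ids)
        else:
            cpd_ids = [f"CPD{i + 1:04d}" for i in range(n_cpd)]
        rows = []
        assigned = {w: cid for w, cid in zip(compound_wells, cpd_ids)}
        for i, w in enumerate(names):
            if w in assigned:
                rows.append((w, "compound", assigned[w], config.screen_concentration_uM))
            elif w in control_wells:
                rows.append((w, "control", "DMSO", 0.0))
            else:
                rows.append((w, "empty", "", np.nan))
        self.layout = pd.DataFrame(
            rows, columns=["well", "role", "compound_id", "concentration_uM"]
        )
        self.layout["library_id"] = config.library_id
        self._well_index = {w: i for i, w in enumerate(names)}

    @property
    def wells(self) -> list[str]:
        """Occupied (control or compound) wells, plate order."""
        return list(self.layout.loc[self.layout.role != "empty", "well"])

    def effect_for(self, well: str) -> CompoundEffectModel:
        row = self.layout.set_index("well").loc[well]
        if row["role"] != "compound":
            return NULL_EFFECT
        return self.config.effects.get(row["compound_id"], NULL_EFFECT)

    def field(self, well: str, field_id: int) -> SimulatedField:
        """Generate (deterministically) one field of one well."""
        cfg = self.config
        _require(0 <= field_id < cfg.n_fields_per_well, "field_id out of range")
        row = self.layout.set_index("well").loc[well]
        if row["role"] == "empty":
            raise ValueError(f"well {well} is empty")
        params, fractions = self.class_params, self.config.population.class_fractions
        if row["role"] == "compound":
            params, fractions = _effective_population(
                params,
                fractions,
                self.effect_for(well),
                cfg.screen_concentration_uM,
            )
        pop = replace(cfg.population, class_fractions=fractions)
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, self._well_index[well], field_id])
        )
        return simulate_field(pop, class_params=params, rng=rng)

    def iter_fields(self) -> Iterator[tuple[str, int, SimulatedField]]:
        for well in self.wells:
            for f in range(self.config.n_fields_per_well):
                yield well, f, self.field(well, f)


def simulate_plate(
    cfg: PlateSimConfig,
    class_params: Mapping[str, MotilityClassParams] | None = None,
) -> PlateSimulation:
    """Build the lazy simulation of one 384-well screening plate."""
    return PlateSimulation(cfg, class_params)


# ---------------------------------------------------------------------------
# dose-response responses


def simulate_dose_response(
    effect: CompoundEffectModel,
    series: DoseSeries | None = None,
    n_replicate_experiments: int = 2,
    n_replicates_per_concentration: int = 2,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate % of control responses over a dilution series.

    Each experiment models an independent biological replicate (its own
    donor pool): responses are the effect model's expected % of control
    plus independent additive Gaussian noise (default SD 5 percentage
    points).  Columns: experiment_id, concentration_uM, replicate,
    percent_of_control, true_percent_of_control.
    """
    _require(n_replicate_experiments >= 1, "need at least one experiment")
    _require(n_replicates_per_concentration >= 1, "need at least one replicate")
    _require(noise_sd >= 0, "noise_sd must be >= 0")
    if series is None:
        series = DoseSeries()
    conc = dilution_series(series)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    frames = []
    truth = true_percent_of_control(effect, conc)
    for e in range(n_replicate_experiments):
        for r in range(n_replicates_per_concentration):
            resp = truth + rng.normal(0.0, noise_sd, size=conc.size)
            frames.append(
                pd.DataFrame(
                    {
                        "experiment_id": e + 1,
                        "concentration_uM": conc,
                        "replicate": r + 1,
                        "percent_of_control": resp,
                        "true_percent_of_control": truth,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# optional frame rendering (exercises the image-detection stage)


def render_frames(
    field: SimulatedField,
    pixel_size_um: float = 1.4,
    spot_sigma_um: float = 2.0,
    amplitude: float = 1000.0,
    background: float = 100.0,
    noise_sd: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a field's detections as a (n_frames, H, W) image stack.

    Each detection becomes an isotropic Gaussian spot; Gaussian read
    noise is added on a flat background.  Intended for round-trip tests
    of the spot detector, not for photorealism.
    """
    cfg = field.config
    w_px = int(math.ceil(cfg.field_size[0] / pixel_size_um))
    h_px = int(math.ceil(cfg.field_size[1] / pixel_size_um))
    rng = np.random.default_rng(seed)
    stack = np.full((cfg.n_frames, h_px, w_px), background, dtype=float)
    sig_px = spot_sigma_um / pixel_size_um
    half = int(math.ceil(4 * sig_px))
    win = np.arange(-half, half + 1)
    det = field.detections
    for f, x, y in zip(det["frame"].to_numpy(), det["x_um"].to_numpy(), det["y_um"].to_numpy()):
        cx, cy = x / pixel_size_um, y / pixel_size_um
        ix, iy = int(round(cx)), int(round(cy))
        xs, ys = win + ix, win + iy
        ok_x = (xs >= 0) & (xs < w_px)
        ok_y = (ys >= 0) & (ys < h_px)
        if not (ok_x.any() and ok_y.any()):
            continue
        gx = np.exp(-0.5 * ((xs[ok_x] - cx) / sig_px) ** 2)
        gy = np.exp(-0.5 * ((ys[ok_y] - cy) / sig_px) ** 2)
        stack[int(f), np.ix_(ys[ok_y], xs[ok_x])[0], np.ix_(ys[ok_y], xs[ok_x])[1]] += (
            amplitude * gy[:, None] * gx[None, :]
        )
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
    return stack


def save_frames_tiff(stack: np.ndarray, path) -> None:
    """Write a rendered frame stack as a multi-page 16-bit TIFF."""
    import tifffile

    clipped = np.clip(stack, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, clipped)


def load_frames_tiff(path) -> np.ndarray:
    """Read a multi-page TIFF back as a float frame stack."""
    import tifffile

    return tifffile.imread(path).astype(float)
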