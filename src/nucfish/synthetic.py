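"""Seeded synthetic data with ground truth for every generated object.

This module emulates the statistical structure of amplified nuclear RNA FISH
experiments: isolated nuclei carrying a small number of bright transcription-
site foci (colocalized exon+intron puncta) plus dimmer single-RNA spots,
per-round exponential signal amplification at a configurable binding
efficiency, flow-sorter event fluorescence coupled to transcriptional
activity, and qPCR fold-enrichment (FE) tables with a gate-dependent
chromatin-accessibility effect at a target gene and none at a control gene.

Every generator takes one explicit seed and routes all randomness through a
single ``numpy.random.Generator``, so identical configuration and seed give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .spots import ImageStack

# axial footprint of a punctum: weight per plane at z-1, z, z+1.  The center
# weight is exactly 1 so the noise-free peak voxel value is background +
# amplitude, which downstream per-plane 2D fits rely on.
AXIAL_PROFILE: tuple[tuple[int, float], ...] = ((-1, 0.5), (0, 1.0), (1, 0.5))

CountDist = int | tuple[str, float]


def _draw_counts(spec: CountDist, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw per-nucleus object counts from a distribution spec.

    ``spec`` is either a constant nonnegative int or ``("poisson", mean)``.
    """
    if isinstance(spec, int):
        if spec < 0:
            raise ValueError("constant count must be nonnegative")
        return np.full(n, spec, dtype=int)
    name, mean = spec
    if name != "poisson":
        raise ValueError(f"unknown count distribution {name!r}")
    if mean < 0:
        raise ValueError("poisson mean must be nonnegative")
    return rng.poisson(mean, size=n)


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise on the signal plus Gaussian read noise.

    ``poisson_scale`` converts intensity units to photon counts (0 disables
    shot noise); ``read_sigma`` is the additive Gaussian sd in intensity units.
    """

    poisson_scale: float = 1.0
    read_sigma: float = 20.0

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.read_sigma < 0:
            raise ValueError("noise parameters must be nonnegative")

    @property
    def enabled(self) -> bool:
        return self.poisson_scale > 0 or self.read_sigma > 0

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = image
        if self.poisson_scale > 0:
            out = rng.poisson(out * self.poisson_scale) / self.poisson_scale
        if self.read_sigma > 0:
            out = out + rng.normal(0.0, self.read_sigma, size=out.shape)
        return np.clip(out, 0.0, None)


NO_NOISE = NoiseModel(poisson_scale=0.0, read_sigma=0.0)


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of one synthetic multi-channel scene.

    Defaults reflect the target system: HeLa-like nuclei averaging 1.5
    transcription sites each, imaged at 144 nm/pixel, with transcription-site
    foci 5x brighter than single-RNA spots (the focus/spot intensity ratio is
    a modelling choice exposed here, not a measured constant).
    """

    image_shape: tuple[int, int, int] = (5, 256, 256)  # (z, y, x)
    pixel_size_nm: float = 144.0
    n_nuclei: int = 6
    nucleus_radius_px: tuple[float, float] = (25.0, 2.0)  # (mean, sd)
    txn_sites_per_nucleus: CountDist = ("poisson", 1.5)
    single_spots_per_nucleus: CountDist = ("poisson", 20.0)
    spot_sigma_px: float = 1.3
    site_amplitude: float = 1000.0
    spot_amplitude: float = 200.0
    background_level: float = 100.0
    dapi_amplitude: float = 500.0
    min_spot_separation_px: float = 0.0  # 0 = uniform placement (spots may overlap)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.image_shape) != 3 or any(s < 1 for s in self.image_shape):
            raise ValueError("image_shape must be 3 components, each >= 1")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be nonnegative")
        if self.nucleus_radius_px[0] <= 0 or self.nucleus_radius_px[1] < 0:
            raise ValueError("nucleus radius mean must be positive, sd nonnegative")
        for name in ("spot_sigma_px", "site_amplitude", "spot_amplitude",
                     "dapi_amplitude", "pixel_size_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_level < 0:
            raise ValueError("background_level must be nonnegative")
        if self.min_spot_separation_px < 0:
            raise ValueError("min_spot_separation_px must be nonnegative")


@dataclass
class GroundTruth:
    """True objects underlying a generated dataset.

    ``spots`` lists every rendered punctum (transcription sites contribute one
    exon and one intron row at identical true centers); ``sites`` lists the
    exon-intron pairs; ``events`` and ``fe_table`` are filled by the flow/qPCR
    generators.
    """

    spots: pd.DataFrame = field(default_factory=pd.DataFrame)
    sites: pd.DataFrame = field(default_factory=pd.DataFrame)
    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    fe_table: pd.DataFrame = field(default_factory=pd.DataFrame)


SPOT_COLUMNS = ["nucleus_id", "channel", "z", "y", "x", "amplitude", "is_txn_site"]
SITE_COLUMNS = ["site_id", "nucleus_id", "z", "y", "x"]


def _place_nuclei(
    cfg: SceneConfig, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """Sample non-overlapping disc (cy, cx, radius) triples by rejection."""
    ny, nx = cfg.image_shape[1], cfg.image_shape[2]
    mu, sd = cfg.nucleus_radius_px
    placed: list[tuple[float, float, float]] = []
    max_tries = 2000 * max(cfg.n_nuclei, 1)
    tries = 0
    while len(placed) < cfg.n_nuclei:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {cfg.n_nuclei} non-overlapping nuclei of radius "
                f"~{mu} px in a {ny}x{nx} image after {max_tries} tries; reduce "
                "n_nuclei or nucleus_radius_px, or enlarge image_shape"
            )
        tries += 1
        r = max(3.0, rng.normal(mu, sd))
        cy = rng.uniform(r + 1, ny - r - 1) if ny > 2 * (r + 1) else None
        cx = rng.uniform(r + 1, nx - r - 1) if nx > 2 * (r + 1) else None
        if cy is None or cx is None:
            raise RuntimeError(
                f"nucleus radius ~{mu} px does not fit in a {ny}x{nx} image; "
                "reduce nucleus_radius_px or enlarge image_shape"
            )
        if all(
            math.hypot(cy - py, cx - px) >= r + pr + 2.0 for py, px, pr in placed
        ):
            placed.append((cy, cx, r))
    return placed


def _render_punctum(
    volume: np.ndarray, z: int, y: float, x: float, amplitude: float, sigma: float
) -> None:
    """Add a 2D Gaussian punctum with the fixed 3-plane axial profile in place."""
    nz, ny, nx = volume.shape
    half = max(3, int(math.ceil(5 * sigma)))
    y0, y1 = max(0, int(y) - half), min(ny, int(y) + half + 1)
    x0, x1 = max(0, int(x) - half), min(nx, int(x) + half + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yg, xg = np.mgrid[y0:y1, x0:x1].astype(float)
    blob = amplitude * np.exp(-((yg - y) ** 2 + (xg - x) ** 2) / (2 * sigma**2))
    for dz, w in AXIAL_PROFILE:
        zp = z + dz
        if 0 <= zp < nz:
            volume[zp, y0:y1, x0:x1] += w * blob


def generate_scene(cfg: SceneConfig) -> tuple[ImageStack, np.ndarray, GroundTruth]:
    """Render a 3-channel (DAPI, exon, intron) stack with ground truth.

    Nuclei are non-overlapping filled discs in the DAPI channel (replicated
    over z).  Each transcription site renders one exon and one intron punctum
    at the same (z, y, x); single-RNA spots render in the exon channel only.
    Returns the stack, a 2D nuclear label mask (0 = background, k >= 1 =
    nucleus k) and the ground-truth tables.
    """
    rng = np.random.default_rng(cfg.seed)
    nz, ny, nx = cfg.image_shape
    stack = np.zeros((3, nz, ny, nx), dtype=float)
    mask = np.zeros((ny, nx), dtype=np.uint16)

    nuclei = _place_nuclei(cfg, rng)
    for k, (cy, cx, r) in enumerate(nuclei, start=1):
        y0, y1 = max(0, int(cy - r) - 1), min(ny, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r) - 1), min(nx, int(cx + r) + 2)
        yg, xg = np.mgrid[y0:y1, x0:x1].astype(float)
        disc = (yg - cy) ** 2 + (xg - cx) ** 2 <= r * r
        mask[y0:y1, x0:x1][disc] = k
        stack[0, :, y0:y1, x0:x1][:, disc] += cfg.dapi_amplitude

    n = len(nuclei)
    n_sites = _draw_counts(cfg.txn_sites_per_nucleus, rng, n)
    n_singles = _draw_counts(cfg.single_spots_per_nucleus, rng, n)

    spot_rows: list[tuple] = []
    site_rows: list[tuple] = []
    site_id = 0
    for k, (cy, cx, r) in enumerate(nuclei, start=1):
        margin = 2.0 * cfg.spot_sigma_px + 1.0
        r_eff = max(r - margin, 1.0)
        total = n_sites[k - 1] + n_singles[k - 1]
        # uniform positions inside the shrunken disc; optionally rejection-
        # sampled to keep puncta at least min_spot_separation_px apart
        ys = np.empty(total)
        xs = np.empty(total)
        min_sep = cfg.min_spot_separation_px
        for i in range(total):
            for _ in range(200):
                theta = rng.uniform(0, 2 * math.pi)
                rad = r_eff * math.sqrt(rng.uniform(0, 1))
                y, x = cy + rad * math.sin(theta), cx + rad * math.cos(theta)
                if min_sep == 0 or i == 0 or np.all(
                    np.hypot(ys[:i] - y, xs[:i] - x) >= min_sep
                ):
                    break
            else:
                raise RuntimeError(
                    f"could not place {total} puncta with "
                    f"min_spot_separation_px={min_sep} in a radius-{r:.1f} nucleus"
                )
            ys[i], xs[i] = y, x
        zs = rng.integers(0, nz, total)
        for i in range(total):
            z, y, x = int(zs[i]), float(ys[i]), float(xs[i])
            if i < n_sites[k - 1]:
                _render_punctum(stack[1], z, y, x, cfg.site_amplitude, cfg.spot_sigma_px)
                _render_punctum(stack[2], z, y, x, cfg.site_amplitude, cfg.spot_sigma_px)
                spot_rows.append((k, "exon", z, y, x, cfg.site_amplitude, True))
                spot_rows.append((k, "intron", z, y, x, cfg.site_amplitude, True))
                site_rows.append((site_id, k, z, y, x))
                site_id += 1
            else:
                _render_punctum(stack[1], z, y, x, cfg.spot_amplitude, cfg.spot_sigma_px)
                spot_rows.append((k, "exon", z, y, x, cfg.spot_amplitude, False))

    stack[1] += cfg.background_level
    stack[2] += cfg.background_level
    stack[0] += cfg.background_level

    if cfg.noise_model.enabled:
        stack = cfg.noise_model.apply(stack, rng)

    truth = GroundTruth(
        spots=pd.DataFrame(spot_rows, columns=SPOT_COLUMNS),
        sites=pd.DataFrame(site_rows, columns=SITE_COLUMNS),
    )
    image = ImageStack(
        voxels=stack,
        pixel_size_nm=cfg.pixel_size_nm,
        channel_names=("dapi", "exon", "intron"),
    )
    return image, mask, truth


# ---------------------------------------------------------------------------
# amplification kinetics


@dataclass(frozen=True)
class AmplificationConfig:
    """Per-round spot-intensity sampling for exponential amplification.

    Each amplification round ideally doubles probe binding sites; the realized
    per-round intensity fold is ``2 * binding_efficiency``.  Rounds default to
    the 2/4/6/8 stopping points of the staged amplification protocol.
    """

    rounds: tuple[int, ...] = (2, 4, 6, 8)
    binding_efficiency: float = 0.871
    base_amplitude: float = 100.0
    spots_per_round: int = 200
    intensity_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.rounds) < 2 or any(
            b <= a for a, b in zip(self.rounds, self.rounds[1:])
        ):
            raise ValueError("rounds must be strictly increasing with >= 2 entries")
        if not (0 < self.binding_efficiency <= 1):
            raise ValueError("binding_efficiency must be in (0, 1]")
        if self.base_amplitude <= 0:
            raise ValueError("base_amplitude must be positive")
        if self.spots_per_round < 1:
            raise ValueError("spots_per_round must be >= 1")
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be nonnegative")

    @property
    def fold_per_round(self) -> float:
        return 2.0 * self.binding_efficiency


def generate_amplification_series(cfg: AmplificationConfig):
    """Sample per-round spot intensities with a known true fold.

    Per-round samples are mean-preserving lognormal around
    ``base_amplitude * fold ** ((round - rounds[0]) / step)`` with coefficient
    of variation ``intensity_cv`` (cv = 0 gives exact means).  Returns an
    (uncompleted) :class:`~nucfish.kinetics.AmplificationSeries` and the true
    per-round fold ``2 * binding_efficiency``.
    """
    from .kinetics import AmplificationSeries

    rng = np.random.default_rng(cfg.seed)
    steps = np.diff(cfg.rounds)
    step = int(steps.min())
    fold = cfg.fold_per_round
    intensities = []
    for r in cfg.rounds:
        mean = cfg.base_amplitude * fold ** ((r - cfg.rounds[0]) / step)
        if cfg.intensity_cv == 0:
            samples = np.full(cfg.spots_per_round, mean)
        else:
            sigma = math.sqrt(math.log(1.0 + cfg.intensity_cv**2))
            samples = mean * np.exp(
                rng.normal(-0.5 * sigma**2, sigma, cfg.spots_per_round)
            )
        intensities.append(samples)
    series = AmplificationSeries(rounds=cfg.rounds, intensities=intensities)
    return series, fold


# ---------------------------------------------------------------------------
# flow sorting + qPCR coupling


@dataclass(frozen=True)
class FlowSimConfig:
    """Flow-sorter events from ordered latent activity classes.

    Each latent class k draws ``n_events`` log10-fluorescence values from
    ``Normal(gate_means[k], gate_sds[k])``; per-class qPCR abundance is a
    monotone (linear) function of the class mean fluorescence with
    multiplicative lognormal noise of sd ``qpcr_coupling_noise`` (in log10
    units).  Defaults give three well-separated low/medium/high classes.
    """

    n_events: int = 1000
    gate_means: tuple[float, ...] = (1.0, 2.0, 3.0)  # log10 fluorescence
    gate_sds: tuple[float, ...] = (0.2, 0.2, 0.2)
    qpcr_coupling_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if len(self.gate_means) != len(self.gate_sds):
            raise ValueError("gate_means and gate_sds must have equal length")
        if any(b <= a for a, b in zip(self.gate_means, self.gate_means[1:])):
            raise ValueError("gate_means must be strictly increasing")
        if any(s <= 0 for s in self.gate_sds):
            raise ValueError("gate_sds must be positive")
        if self.qpcr_coupling_noise < 0:
            raise ValueError("qpcr_coupling_noise must be nonnegative")

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(f"G{i + 1}" for i in range(len(self.gate_means)))


def generate_flow_and_qpcr(
    cfg: FlowSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate flow events and matched per-class qPCR abundances.

    Returns an event table (event_id, latent_class, fluorescence), a qPCR
    table (group, abundance) and the combined ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    names = cfg.class_names
    rows = []
    eid = 0
    for k, (m, s) in enumerate(zip(cfg.gate_means, cfg.gate_sds)):
        logf = rng.normal(m, s, cfg.n_events)
        for v in logf:
            rows.append((eid, names[k], 10.0**v))
            eid += 1
    events = pd.DataFrame(rows, columns=["event_id", "latent_class", "fluorescence"])

    class_mean_fluor = np.array([10.0**m for m in cfg.gate_means])
    noise = (
        10.0 ** rng.normal(0.0, cfg.qpcr_coupling_noise, len(names))
        if cfg.qpcr_coupling_noise > 0
        else np.ones(len(names))
    )
    qpcr = pd.DataFrame(
        {"group": list(names), "abundance": class_mean_fluor * noise}
    )
    truth = GroundTruth(events=events.copy())
    return events, qpcr, truth


# ---------------------------------------------------------------------------
# chromatin-accessibility FE tables

TARGET_GENE = "EEF2"
CONTROL_GENE = "UBC"
AMPLICONS = ("5'UTR", "intron", "3'UTR")


def generate_fe_table(
    effect_size: float,
    n_replicates: int = 6,
    noise_sd: float = 0.2,
    gates: Sequence[str] = ("G1", "G2", "G3"),
    base_fe_target: float = 6.0,
    base_fe_control: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a fold-enrichment table with a gate-dependent target effect.

    ``effect_size`` is the FE decrease of the target gene per gate step (lower
    FE means a more accessible locus, since relative accessibility is
    ``2 ** -(FE_target - U_mean)``); the control gene's FE is identically
    distributed across gates.  Three amplicons (5'UTR, intron, 3'UTR) are
    simulated per gene, gate and replicate.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        for g_idx, gate in enumerate(gates):
            for amp in AMPLICONS:
                fe_c = base_fe_control + rng.normal(0.0, noise_sd)
                rows.append((CONTROL_GENE, amp, gate, rep, fe_c))
                fe_t = base_fe_target - effect_size * g_idx + rng.normal(0.0, noise_sd)
                rows.append((TARGET_GENE, amp, gate, rep, fe_t))
    return pd.DataFrame(rows, columns=["gene", "amplicon", "group", "replicate", "FE"])
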