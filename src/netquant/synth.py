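"""Synthetic fluorescence fields and patches with exact ground truth.

The generator emulates SYTOX-stained neutrophil nuclei in 16-bit
wide-field images, at the three morphologies the classifiers must tell
apart:

* **non-NETotic** (label 1) — compact, bright, multilobulated: 2–4
  partially overlapping elliptical lobes with sharp edges;
* **NETotic** (label 2) — swollen, spherical/ovoid, with a markedly diffuse
  signal: a single large blob with heavy decondensation blur;
* **necrotic** (label 3) — a swollen dim body containing several small,
  very bright chromatin clumps.

Every nucleus is a sum of anisotropic 2-D Gaussian components; the
decondensation blur is folded into the component covariance analytically
and conserves integrated intensity, so decondensed chromatin is spread out
and therefore dimmer, as in the real stain. A Poisson shot-noise plus
Gaussian read-noise background completes the image. All randomness flows
from the spec's seed, so identical specs render bit-identical images.

A single ``difficulty`` dial in [0, 1] interpolates every class's
morphological parameter ranges toward a common overlapping regime: at 0 the
classes are cleanly separated (linearly separable on area / solidity / peak
intensity as measured by the rule-based baseline), at 1 they are nearly
indistinguishable. NETotic nuclei additionally carry a treatment subtype
(PMA-like ROS pathway vs A23187-like calcium-ionophore pathway) expressed
as a small eccentricity/texture offset whose size is set by
``subtype_separation`` (0 = identical, 1 = fully separated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .dose import four_pl
from .errors import PlacementError, ValidationError
from .fieldio import NECROTIC_LABEL, AnnotatedField

__all__ = [
    "NucleusSpec", "FieldSpec", "DoseSeriesSpec",
    "sample_nucleus", "render_nucleus_signal", "render_patch", "render_field",
    "simulate_dose_series", "make_patch_arrays",
    "sample_hardcore_points", "sample_thomas_points",
    "PHENOTYPE_LABELS", "DEFAULT_BACKGROUND",
]

PHENOTYPE_LABELS = {"non_netotic": 1, "netotic": 2, "necrotic": NECROTIC_LABEL}

# (offset counts, Gaussian read-noise sd) of the camera background
DEFAULT_BACKGROUND = (200.0, 60.0)


# ---------------------------------------------------------------------------
# nucleus-level specification and rendering
# ---------------------------------------------------------------------------

@dataclass
class NucleusSpec:
    """Geometry and photometry of one synthetic nucleus.

    ``radius`` is the overall nucleus scale in px; ``peak_intensity`` the
    pre-blur component amplitude in 16-bit counts; ``blur_sigma`` the
    chromatin-decondensation blur in px. ``rng_key`` seeds the per-nucleus
    shape jitter so a spec renders identically every time.
    """

    phenotype: str
    lobe_count: int
    radius: float
    peak_intensity: float
    blur_sigma: float
    subtype: str = "none"
    center: tuple[float, float] = (0.0, 0.0)  # (row, col)
    eccentricity: float = 0.0
    granularity: float = 0.0  # residual chromatin texture (NETotic subtype)
    lobe_offset: float = 0.62  # lobe centre distance as a fraction of radius
    clump_count: int = 0
    body_fraction: float = 0.12
    rng_key: int = 0

    def __post_init__(self):
        if self.phenotype not in PHENOTYPE_LABELS:
            raise ValidationError(f"unknown phenotype {self.phenotype!r}")
        if self.subtype not in ("none", "pma_like", "a23187_like"):
            raise ValidationError(f"unknown subtype {self.subtype!r}")
        if not 0 <= self.peak_intensity <= 65535:
            raise ValidationError("peak_intensity outside [0, 65535]")
        if self.phenotype == "non_netotic" and self.lobe_count < 2:
            raise ValidationError("non-NETotic nuclei must have >= 2 lobes")
        if self.phenotype != "non_netotic" and self.lobe_count != 1:
            raise ValidationError(
                f"{self.phenotype} nuclei are single-lobed (lobe_count=1)")
        if self.phenotype == "necrotic" and self.clump_count < 3:
            raise ValidationError("necrotic nuclei need >= 3 chromatin clumps")
        if self.radius <= 0:
            raise ValidationError("radius must be positive")

    @property
    def label(self) -> int:
        return PHENOTYPE_LABELS[self.phenotype]


def _lerp(a, b, t):
    return a + (b - a) * t


def _u(rng, lo, hi):
    return float(rng.uniform(lo, hi))


def sample_nucleus(phenotype: str, difficulty: float = 0.0,
                   rng: np.random.Generator | None = None,
                   subtype: str = "none",
                   subtype_separation: float = 1.0) -> NucleusSpec:
    """Draw a random :class:`NucleusSpec` of the given phenotype.

    ``difficulty`` linearly interpolates each sampled parameter between the
    class's own well-separated range (0) and a shared overlapping range (1).
    """
    if not 0.0 <= difficulty <= 1.0:
        raise ValidationError("difficulty must be in [0, 1]")
    rng = rng or np.random.default_rng()
    d = float(difficulty)
    # the shared "hard" regime all classes collapse toward
    hard_radius = _u(rng, 7.5, 10.0)
    hard_peak = _u(rng, 15000, 24000)
    hard_blur = _u(rng, 1.4, 2.2)
    key = int(rng.integers(2**31))
    if phenotype == "non_netotic":
        return NucleusSpec(
            phenotype="non_netotic",
            lobe_count=int(rng.integers(2, 5)),
            radius=_lerp(_u(rng, 5.0, 7.0), hard_radius, d),
            peak_intensity=_lerp(_u(rng, 26000, 34000), hard_peak, d),
            blur_sigma=_lerp(_u(rng, 0.6, 1.0), hard_blur, d),
            lobe_offset=_lerp(0.62, 0.15, d),  # lobes merge as d -> 1
            rng_key=key)
    if phenotype == "netotic":
        if subtype == "none":
            ecc, gran = _u(rng, 0.02, 0.10), 0.0
        else:
            # subtype dial: PMA-like rounder and smooth, A23187-like more
            # elongated with residual chromatin granularity; separation 0
            # collapses both onto the same distribution
            base = 0.14
            shift = 0.26 * subtype_separation
            ecc = abs(rng.normal(
                base + (shift if subtype == "a23187_like" else -shift) / 2,
                0.05))
            gran = (0.55 * subtype_separation * _u(rng, 0.8, 1.2)
                    if subtype == "a23187_like" else 0.0)
        return NucleusSpec(
            phenotype="netotic", lobe_count=1, subtype=subtype,
            radius=_lerp(_u(rng, 10.5, 13.0), hard_radius * 0.8, d),
            peak_intensity=_lerp(_u(rng, 16000, 22000), hard_peak, d),
            blur_sigma=_lerp(_u(rng, 2.6, 3.4), hard_blur, d),
            eccentricity=ecc, granularity=gran, rng_key=key)
    if phenotype == "necrotic":
        return NucleusSpec(
            phenotype="necrotic", lobe_count=1,
            radius=_lerp(_u(rng, 10.0, 14.0), hard_radius, d),
            peak_intensity=_lerp(_u(rng, 42000, 52000), hard_peak * 1.2, d),
            blur_sigma=_lerp(_u(rng, 0.5, 0.8), hard_blur, d),
            clump_count=int(rng.integers(3, 6)),
            body_fraction=_lerp(0.10, 0.5, d),
            rng_key=key)
    raise ValidationError(f"unknown phenotype {phenotype!r}")


def _components(spec: NucleusSpec):
    """Decompose a nucleus into (drow, dcol, sigma_u, sigma_v, angle, amp)
    Gaussian components relative to the nucleus centre."""
    rng = np.random.default_rng(spec.rng_key)
    r = spec.radius
    comps = []
    if spec.phenotype == "non_netotic":
        theta0 = rng.uniform(0, 2 * math.pi)
        dist = spec.lobe_offset * r
        # as lobes merge (small offset) their amplitudes superpose; rescale
        # so the summed peak stays at the specified intensity
        overlap = min(max((0.62 - spec.lobe_offset) / 0.47, 0.0), 1.0)
        merge_norm = 1.0 + (spec.lobe_count - 1) * overlap
        for k in range(spec.lobe_count):
            ang = theta0 + 2 * math.pi * k / spec.lobe_count
            amp = spec.peak_intensity * rng.uniform(0.85, 1.0) / merge_norm
            comps.append((dist * math.sin(ang), dist * math.cos(ang),
                          0.42 * r, 0.30 * r, ang, amp))
    elif spec.phenotype == "netotic":
        ang = rng.uniform(0, 2 * math.pi)
        e = spec.eccentricity
        comps.append((0.0, 0.0, 0.52 * r * (1 + e), 0.52 * r * (1 - e),
                      ang, spec.peak_intensity))
        if spec.granularity > 0:
            # faint bright speckles of not-fully-decondensed chromatin
            for _ in range(4):
                sang = rng.uniform(0, 2 * math.pi)
                dist = rng.uniform(0.1, 0.5) * r
                comps.append((dist * math.sin(sang), dist * math.cos(sang),
                              2.5, 2.5, 0.0,
                              spec.granularity * spec.peak_intensity))
    else:  # necrotic: dim swollen body plus bright chromatin clumps
        comps.append((0.0, 0.0, 0.55 * r, 0.55 * r, 0.0,
                      spec.peak_intensity * spec.body_fraction))
        for _ in range(spec.clump_count):
            ang = rng.uniform(0, 2 * math.pi)
            dist = rng.uniform(0.1, 0.55) * r
            cs = rng.uniform(1.7, 2.4)
            comps.append((dist * math.sin(ang), dist * math.cos(ang),
                          cs, cs, 0.0, spec.peak_intensity))
    return comps


def render_nucleus_signal(spec: NucleusSpec, shape: tuple[int, int],
                          center: tuple[float, float]) -> np.ndarray:
    """Noise-free photon-rate image of one nucleus on a zero background.

    The decondensation blur is folded into each Gaussian component's widths
    with conserved integral: sigma' = sqrt(sigma^2 + blur^2) and the
    amplitude scales by (sigma_u sigma_v) / (sigma_u' sigma_v').
    """
    h, w = shape
    out = np.zeros((h, w), dtype=np.float64)
    cr, cc = center
    b2 = spec.blur_sigma ** 2
    for drow, dcol, su, sv, ang, amp in _components(spec):
        su2, sv2 = math.sqrt(su * su + b2), math.sqrt(sv * sv + b2)
        amp2 = amp * (su * sv) / (su2 * sv2)
        mr, mc = cr + drow, cc + dcol
        ext = 3.5 * max(su2, sv2)
        r0, r1 = max(0, int(mr - ext)), min(h, int(mr + ext) + 2)
        c0, c1 = max(0, int(mc - ext)), min(w, int(mc + ext) + 2)
        if r0 >= r1 or c0 >= c1:
            continue
        rows = np.arange(r0, r1, dtype=np.float64)[:, None] - mr
        cols = np.arange(c0, c1, dtype=np.float64)[None, :] - mc
        ca, sa = math.cos(ang), math.sin(ang)
        u = rows * ca - cols * sa
        v = rows * sa + cols * ca
        out[r0:r1, c0:c1] += amp2 * np.exp(
            -0.5 * ((u / su2) ** 2 + (v / sv2) ** 2))
    return out


def _apply_camera(signal: np.ndarray, background: tuple[float, float],
                  rng: np.random.Generator, noise: bool = True) -> np.ndarray:
    offset, sd = background
    if noise:
        img = rng.poisson(signal).astype(np.float64)
        img += rng.normal(offset, sd, size=signal.shape)
    else:
        img = signal + offset
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def render_patch(spec: NucleusSpec, size: int, seed: int | None = 0,
                 background: tuple[float, float] = DEFAULT_BACKGROUND,
                 noise: bool = True) -> np.ndarray:
    """Render one nucleus centred in a ``size x size`` uint16 patch."""
    margin = 2.0
    if 2 * spec.radius + margin > size:
        raise ValidationError(
            f"nucleus radius {spec.radius} px does not fit a {size} px patch")
    signal = render_nucleus_signal(spec, (size, size),
                                   (size / 2.0, size / 2.0))
    return _apply_camera(signal, background, np.random.default_rng(seed),
                         noise=noise)


# ---------------------------------------------------------------------------
# field-level specification and rendering
# ---------------------------------------------------------------------------

@dataclass
class FieldSpec:
    """Recipe for one synthetic field.

    ``phenotype_fractions`` is (non-NETotic, NETotic, necrotic) and must sum
    to 1; per-phenotype counts are fixed by largest-remainder rounding of
    ``fraction * n_nuclei``, so they are deterministic. ``point_process``
    selects dispersed (``hardcore_poisson``: no two centres closer than
    ``hardcore_distance``) or clustered (``thomas_cluster``: offspring
    scattered around Poisson parents with ``cluster_sigma``) placement.
    """

    height: int = 512
    width: int = 672
    n_nuclei: int = 50
    phenotype_fractions: tuple[float, float, float] = (0.5, 0.5, 0.0)
    point_process: str = "hardcore_poisson"
    hardcore_distance: float = 28.0
    cluster_params: tuple[float, float, float] = (8.0, 10.0, 25.0)
    background: tuple[float, float] = DEFAULT_BACKGROUND
    difficulty: float = 0.0
    netotic_subtype: str = "none"
    subtype_separation: float = 1.0
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.phenotype_fractions, dtype=float)
        if len(f) != 3 or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValidationError(
                "phenotype_fractions must be 3 non-negative values summing to 1")
        if self.point_process not in ("hardcore_poisson", "thomas_cluster"):
            raise ValidationError(
                f"unknown point process {self.point_process!r}")
        if self.height < 1 or self.width < 1 or self.n_nuclei < 0:
            raise ValidationError("field dimensions/counts must be positive")


def _phenotype_counts(fractions, n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n nuclei over the 3 phenotypes."""
    names = ("non_netotic", "netotic", "necrotic")
    raw = np.asarray(fractions, dtype=float) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return dict(zip(names, base))


def sample_hardcore_points(n: int, height: float, width: float,
                           margin, min_distance: float,
                           rng: np.random.Generator,
                           max_attempts_per_point: int = 500) -> np.ndarray:
    """Sequential-inhibition sample of ``n`` (row, col) points with pairwise
    distance >= ``min_distance``; ``margin`` is scalar or per-point array."""
    margin = np.broadcast_to(np.asarray(margin, dtype=float), (n,))
    pts = np.empty((0, 2))
    for i in range(n):
        m = margin[i]
        if height - 2 * m <= 0 or width - 2 * m <= 0:
            raise PlacementError(
                f"margin {m} px leaves no room in a {height}x{width} field")
        for _ in range(max_attempts_per_point):
            cand = np.array([rng.uniform(m, height - m),
                             rng.uniform(m, width - m)])
            if len(pts) == 0 or (np.linalg.norm(pts - cand, axis=1)
                                 >= min_distance).all():
                pts = np.vstack([pts, cand])
                break
        else:
            raise PlacementError(
                f"could not place point {i + 1}/{n} with min distance "
                f"{min_distance} px in a {height}x{width} field "
                f"(margin {m} px): hard-core constraint unsatisfiable")
    return pts


def sample_thomas_points(n: int, height: float, width: float, margin,
                         parent_rate: float, cluster_sigma: float,
                         rng: np.random.Generator,
                         max_attempts: int = 100_000) -> np.ndarray:
    """Thomas-process sample conditioned on a fixed total count ``n``:
    Poisson(parent_rate) cluster centres (at least 1), offspring scattered
    isotropically with sd ``cluster_sigma`` and rejected outside margins."""
    margin = np.broadcast_to(np.asarray(margin, dtype=float), (n,))
    n_parents = max(1, int(rng.poisson(parent_rate)))
    m0 = float(margin.max(initial=0.0))
    parents = np.column_stack([
        rng.uniform(m0, height - m0, n_parents),
        rng.uniform(m0, width - m0, n_parents)])
    pts = np.empty((n, 2))
    placed = 0
    for _ in range(max_attempts):
        if placed >= n:
            break
        p = parents[rng.integers(n_parents)]
        cand = p + rng.normal(0, cluster_sigma, 2)
        m = margin[placed]
        if m <= cand[0] <= height - m and m <= cand[1] <= width - m:
            pts[placed] = cand
            placed += 1
    if placed < n:
        raise PlacementError(
            f"Thomas sampler placed only {placed}/{n} points inside margins")
    return pts


def render_field(spec: FieldSpec) -> AnnotatedField:
    """Render a full synthetic field with one annotation per nucleus.

    Labels follow ``PHENOTYPE_LABELS`` (1 non-NETotic, 2 NETotic,
    3 necrotic). Identical spec (including seed) renders a bit-identical
    image and annotation table.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _phenotype_counts(spec.phenotype_fractions, spec.n_nuclei)
    phenotypes = [p for p, c in counts.items() for _ in range(c)]
    rng.shuffle(phenotypes)
    nuclei = [
        sample_nucleus(
            p, spec.difficulty, rng,
            subtype=spec.netotic_subtype if p == "netotic" else "none",
            subtype_separation=spec.subtype_separation)
        for p in phenotypes
    ]
    margins = np.array([nuc.radius + 1.0 for nuc in nuclei])
    if spec.n_nuclei:
        if spec.point_process == "hardcore_poisson":
            pts = sample_hardcore_points(spec.n_nuclei, spec.height,
                                         spec.width, margins,
                                         spec.hardcore_distance, rng)
        else:
            parent_rate, _, cluster_sigma = spec.cluster_params
            pts = sample_thomas_points(spec.n_nuclei, spec.height, spec.width,
                                       margins, parent_rate, cluster_sigma,
                                       rng)
    else:
        pts = np.empty((0, 2))
    signal = np.zeros((spec.height, spec.width), dtype=np.float64)
    rows = []
    for nuc, (r, c) in zip(nuclei, pts):
        signal += render_nucleus_signal(nuc, signal.shape, (r, c))
        rows.append({"x": int(round(c)), "y": int(round(r)),
                     "label": nuc.label})
    image = _apply_camera(signal, spec.background, rng)
    ann = pd.DataFrame(rows, columns=["x", "y", "label"]).astype(int)
    return AnnotatedField(image=image, annotations=ann,
                          provenance={"spec": spec.__dict__.copy()},
                          field_id=f"synth_{spec.seed}")


def make_patch_arrays(class_names: list[str], n_per_class: int, size: int,
                      difficulty: float = 0.0, seed: int = 0,
                      subtypes: dict[str, str] | None = None,
                      subtype_separation: float = 1.0,
                      background: tuple[float, float] = DEFAULT_BACKGROUND,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Render a labelled patch stack for classifier experiments.

    ``class_names`` entries are phenotypes or ``"background"`` (a patch with
    no nucleus); returned labels are indices into ``class_names``. Patches
    are uint16 of shape ``(len(class_names) * n_per_class, size, size)``,
    interleaved and then fixed in order (class blocks), so stratified
    splitting downstream sees balanced classes.
    """
    rng = np.random.default_rng(seed)
    patches = np.empty((len(class_names) * n_per_class, size, size),
                       dtype=np.uint16)
    labels = np.empty(len(class_names) * n_per_class, dtype=np.int64)
    i = 0
    for ci, name in enumerate(class_names):
        for _ in range(n_per_class):
            if name == "background":
                patch = _apply_camera(np.zeros((size, size)), background, rng)
            else:
                sub = (subtypes or {}).get(name, "none")
                nuc = sample_nucleus(name, difficulty, rng, subtype=sub,
                                     subtype_separation=subtype_separation)
                sig = render_nucleus_signal(nuc, (size, size),
                                            (size / 2.0, size / 2.0))
                patch = _apply_camera(sig, background, rng)
            patches[i] = patch
            labels[i] = ci
            i += 1
    return patches, labels


# ---------------------------------------------------------------------------
# dose-response simulation
# ---------------------------------------------------------------------------

@dataclass
class DoseSeriesSpec:
    """Per-well %NETotic responses following a 4PL dose law.

    Each well draws its NETotic count binomially (``cells_per_well`` cells
    at the 4PL mean fraction; ``None`` = infinite-cell limit) and adds
    Gaussian plate noise of sd ``noise_sd`` percentage points.
    """

    ec50: float
    hill: float = 1.0
    bottom: float = 0.0
    top: float = 100.0
    concentrations: tuple = ()
    cells_per_well: int | None = 200
    n_replicates: int = 2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.bottom < self.top <= 100):
            raise ValidationError("need 0 <= bottom < top <= 100")
        if self.ec50 <= 0:
            raise ValidationError("ec50 must be positive")
        conc = np.asarray(self.concentrations, dtype=float)
        if len(conc) == 0 or np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ValidationError(
                "concentrations must be strictly positive and sorted")


def simulate_dose_series(spec: DoseSeriesSpec) -> pd.DataFrame:
    """Simulate the series; returns columns (concentration, replicate,
    response) with response in % NETotic nuclei."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for x in spec.concentrations:
        mean = four_pl(x, spec.bottom, spec.top, spec.ec50, spec.hill)
        for rep in range(spec.n_replicates):
            if spec.cells_per_well is None:
                resp = float(mean)
            else:
                k = rng.binomial(spec.cells_per_well,
                                 min(max(mean / 100.0, 0.0), 1.0))
                resp = 100.0 * k / spec.cells_per_well
            if spec.noise_sd > 0:
                resp += rng.normal(0.0, spec.noise_sd)
            rows.append({"concentration": float(x), "replicate": rep,
                         "response": resp})
    return pd.DataFrame(rows)
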