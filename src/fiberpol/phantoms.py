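"""Synthetic Mueller-image phantoms of aligned fibrous samples.

The phantoms emulate, at the Mueller-matrix level, the optical behavior of
the sample classes the pipeline is designed for:

* ``nonbirefringent_cylinder`` — aligned non-birefringent cylinders (glass
  fiber): anisotropic scattering produces form birefringence with fast
  axis *parallel* to the fiber long axis, plus diattenuation with
  transmission axis *perpendicular* to it.
* ``pure_birefringent`` — an ordered birefringent medium with negligible
  scattering (air-dried tendon): intrinsic birefringence with fast axis
  *perpendicular* to the fiber long axis, vanishing diattenuation.
* ``birefringent_cylinder`` — birefringent cylinders (silk, fresh tendon,
  muscle): each pixel draws its retarder fast axis from a two-component
  mixture — with probability ``mixture_w`` perpendicular to the fiber
  (intrinsic component), otherwise parallel (form component) — producing
  the cross-perpendicular bimodal fast-axis distribution.

The physical coupling of scattering and lattice birefringence inside one
fiber is modeled phenomenologically as this per-pixel axis mixture rather
than by photon-transport simulation: it reproduces the histogram-level
phenomenology the analysis consumes while keeping every generated pixel
traceable to ground truth. ``mixture_w`` is the generative twin of the
measured share gamma.

Each pixel's matrix is composed in the polar-decomposition factor order
``depolarizer @ retarder @ diattenuator``, so noise-free single-layer
phantoms decompose exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .mueller import depolarizer_diag, linear_diattenuator, linear_retarder, wrap_axial

__all__ = [
    "LayerSpec",
    "PhantomTruth",
    "glass_fiber_spec",
    "air_dried_tendon_spec",
    "silk_spec",
    "layer_matrix",
    "layer_matrices",
    "generate_phantom",
    "crossed_layers_phantom",
    "silk_layer_series",
    "stretch_series",
    "STRETCH_STATES",
]

_KINDS = ("nonbirefringent_cylinder", "pure_birefringent", "birefringent_cylinder")

#: Stretch-state labels: no stretch, transverse (cross) 1-2, longitudinal 1-2.
STRETCH_STATES = ("NS", "CS1", "CS2", "LS1", "LS2")


@dataclass(frozen=True)
class LayerSpec:
    """One fibrous layer: geometry, retardances, diattenuation, depolarization.

    Parameters
    ----------
    kind : str
        One of ``nonbirefringent_cylinder``, ``pure_birefringent``,
        ``birefringent_cylinder``.
    fiber_axis : float
        Fiber long-axis orientation, degrees (axial).
    delta_form, delta_intrinsic : float
        Retardance magnitudes (deg) of the form (axis parallel to fiber)
        and intrinsic (axis perpendicular) components.
    D : float
        Diattenuation magnitude; the transmission axis is fixed
        perpendicular to the fiber.
    depol : tuple of 3 floats
        Diagonal depolarizer coefficients in [0, 1].
    sigma_axis : float
        Wrapped-normal SD (deg) of per-pixel angular noise on the drawn
        fast axis.
    mixture_w : float
        Probability of the intrinsic (perpendicular) component for
        ``birefringent_cylinder`` pixels.
    """

    kind: str
    fiber_axis: float
    delta_form: float = 0.0
    delta_intrinsic: float = 0.0
    D: float = 0.0
    depol: tuple = (1.0, 1.0, 1.0)
    sigma_axis: float = 0.0
    mixture_w: float = 0.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}; expected one of {_KINDS}")
        if self.delta_form < 0 or self.delta_intrinsic < 0:
            raise ValueError("retardance magnitudes must be >= 0")
        if not 0.0 <= self.D <= 1.0:
            raise ValueError("diattenuation D must lie in [0, 1]")
        if len(self.depol) != 3 or any(not 0.0 <= d <= 1.0 for d in self.depol):
            raise ValueError("depol must be three coefficients in [0, 1]")
        if self.sigma_axis < 0:
            raise ValueError("sigma_axis must be >= 0")
        if not 0.0 <= self.mixture_w <= 1.0:
            raise ValueError("mixture_w must lie in [0, 1]")
        if self.kind == "nonbirefringent_cylinder" and self.delta_intrinsic != 0:
            raise ValueError("nonbirefringent_cylinder must have delta_intrinsic = 0")
        if self.kind == "pure_birefringent":
            if self.D > 0.05:
                raise ValueError("pure_birefringent requires D ~ 0 (<= 0.05)")
            if min(self.depol) < 0.9:
                raise ValueError("pure_birefringent requires depol ~ (1, 1, 1) (>= 0.9)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["depol"] = list(self.depol)
        return d


def glass_fiber_spec(fiber_axis: float = 0.0, **overrides) -> LayerSpec:
    """Neatly glued non-birefringent glass fibers (ordered, weakly depolarizing)."""
    spec = LayerSpec(
        kind="nonbirefringent_cylinder", fiber_axis=fiber_axis,
        delta_form=20.0, D=0.1, depol=(0.95, 0.95, 0.90), sigma_axis=3.0,
    )
    return replace(spec, **overrides) if overrides else spec


def air_dried_tendon_spec(fiber_axis: float = 0.0, **overrides) -> LayerSpec:
    """Air-dried tendon: near-transparent, intrinsic birefringence dominates."""
    spec = LayerSpec(
        kind="pure_birefringent", fiber_axis=fiber_axis,
        delta_intrinsic=45.0, D=0.02, depol=(1.0, 1.0, 1.0), sigma_axis=5.0,
    )
    return replace(spec, **overrides) if overrides else spec


def silk_spec(fiber_axis: float = 0.0, mixture_w: float = 0.6, **overrides) -> LayerSpec:
    """Two-layer-silk-like birefringent cylinders with bimodal fast axis."""
    spec = LayerSpec(
        kind="birefringent_cylinder", fiber_axis=fiber_axis,
        delta_form=30.0, delta_intrinsic=30.0, D=0.1,
        depol=(0.90, 0.90, 0.85), sigma_axis=8.0, mixture_w=mixture_w,
    )
    return replace(spec, **overrides) if overrides else spec


def _draw_axes(spec: LayerSpec, n: int, rng: np.random.Generator):
    """Per-pixel retarder fast axes and retardance magnitudes for one layer."""
    noise = rng.normal(0.0, spec.sigma_axis, n) if spec.sigma_axis > 0 else np.zeros(n)
    if spec.kind == "nonbirefringent_cylinder":
        axes = spec.fiber_axis + noise
        deltas = np.full(n, spec.delta_form)
    elif spec.kind == "pure_birefringent":
        axes = spec.fiber_axis + 90.0 + noise
        deltas = np.full(n, spec.delta_intrinsic)
    else:  # birefringent_cylinder: two-component axis mixture
        intrinsic = rng.random(n) < spec.mixture_w
        axes = spec.fiber_axis + np.where(intrinsic, 90.0, 0.0) + noise
        deltas = np.where(intrinsic, spec.delta_intrinsic, spec.delta_form)
    return wrap_axial(axes), deltas


def layer_matrices(spec: LayerSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` per-pixel Mueller matrices for one layer, shape (n, 4, 4)."""
    axes, deltas = _draw_axes(spec, n, rng)
    ret = linear_retarder(deltas, axes)
    diatt = linear_diattenuator(spec.D, wrap_axial(spec.fiber_axis + 90.0))
    dep = depolarizer_diag(*spec.depol)
    return dep @ ret @ diatt


def layer_matrix(spec: LayerSpec, rng: np.random.Generator) -> np.ndarray:
    """Single per-pixel draw of a layer's Mueller matrix."""
    return layer_matrices(spec, 1, rng)[0]


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom image."""

    layers: list
    regions: np.ndarray
    region_layers: dict
    seed: int
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "layers": [s.to_dict() for s in self.layers],
            "regions": np.asarray(self.regions).tolist(),
            "region_layers": {str(k): list(v) for k, v in self.region_layers.items()},
            "seed": self.seed,
            "meta": self.meta,
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def generate_phantom(
    layers,
    shape=(128, 128),
    regions: np.ndarray | None = None,
    region_layers: dict | None = None,
    seed: int = 0,
):
    """Generate a Mueller image by stacking layers over labeled regions.

    Parameters
    ----------
    layers : sequence of LayerSpec
        All layers used anywhere in the image, in light-propagation order.
    shape : (H, W)
    regions : int array (H, W), optional
        Region label per pixel. Defaults to a single region 0 covering the
        image.
    region_layers : dict, optional
        Maps region label -> tuple of indices into ``layers`` active
        there (empty tuple = empty sample, identity matrix). Defaults to
        all layers everywhere. Every label present in ``regions`` must be
        covered.
    seed : int

    Returns
    -------
    (image, truth) : (H, W, 4, 4) array and PhantomTruth
    """
    layers = list(layers)
    H, W = shape
    if regions is None:
        regions = np.zeros((H, W), dtype=int)
    regions = np.asarray(regions)
    if regions.shape != (H, W):
        raise ValueError("regions mask shape must match the image shape")
    if region_layers is None:
        region_layers = {int(r): tuple(range(len(layers))) for r in np.unique(regions)}
    missing = set(np.unique(regions).tolist()) - set(region_layers)
    if missing:
        raise ValueError(f"regions {sorted(missing)} have no layer assignment")

    rng = np.random.default_rng(seed)
    image = np.empty((H, W, 4, 4))
    for label in sorted(region_layers):
        sel = regions == label
        npix = int(sel.sum())
        if npix == 0:
            continue
        acc = np.broadcast_to(np.eye(4), (npix, 4, 4)).copy()
        for idx in region_layers[label]:
            acc = layer_matrices(layers[idx], npix, rng) @ acc
        image[sel] = acc
    truth = PhantomTruth(
        layers=layers, regions=regions,
        region_layers={int(k): tuple(v) for k, v in region_layers.items()},
        seed=int(seed),
        meta={"mixture_w": [s.mixture_w for s in layers]},
    )
    return image, truth


def crossed_layers_phantom(
    spec0: LayerSpec,
    spec1: LayerSpec,
    shape=(128, 128),
    seed: int = 0,
):
    """Two layers stacked with an overlap strip (serial combination geometry).

    The image is split into three vertical strips: only layer 0, both
    layers (overlap, layer 0 encountered first), only layer 1 — the
    geometry of a two-layer crossed-fiber experiment.
    """
    H, W = shape
    regions = np.zeros((H, W), dtype=int)
    regions[:, W // 3: 2 * W // 3] = 1
    regions[:, 2 * W // 3:] = 2
    region_layers = {0: (0,), 1: (0, 1), 2: (1,)}
    return generate_phantom(
        [spec0, spec1], shape=shape, regions=regions,
        region_layers=region_layers, seed=seed,
    )


def silk_layer_series(
    n_layers=(2, 4, 6, 8, 10),
    base_spec: LayerSpec | None = None,
    shape=(128, 128),
    seed: int = 0,
    rho: float = 0.85,
):
    """Phantoms emulating silk wound in increasing numbers of layers.

    Layer count L scales the diagonal depolarizer coefficients to their
    L-th elementwise power (each pass depolarizes further) and shrinks the
    intrinsic mixture share as ``w_L = w_1 * rho**(L - 1)`` (multiple
    scattering progressively buries the intrinsic-birefringence signal).
    The schedule is recorded in each truth's ``meta``.
    """
    base = base_spec if base_spec is not None else silk_spec()
    if base.kind != "birefringent_cylinder":
        raise ValueError("silk_layer_series requires a birefringent_cylinder spec")
    out = []
    for i, L in enumerate(n_layers):
        if L < 1:
            raise ValueError("layer counts must be >= 1")
        w_L = base.mixture_w * rho ** (L - 1)
        spec = replace(
            base, depol=tuple(d**L for d in base.depol), mixture_w=w_L
        )
        image, truth = generate_phantom([spec], shape=shape, seed=seed + i)
        truth.meta.update({"n_layers": int(L), "scheduled_w": w_L, "rho": rho})
        out.append((image, truth))
    return out


def stretch_series(
    base_spec: LayerSpec | None = None,
    shape=(128, 128),
    seed: int = 0,
    delta_w: float = 0.15,
):
    """Five-state stretch sweep of the intrinsic mixture share.

    Transverse stretching (CS1, CS2) packs more overlapping filaments per
    unit length, strengthening form birefringence (w decreases);
    longitudinal stretching (LS1, LS2) does the opposite. The scheduled
    shares are ``w0 + k * delta_w`` for k = 0, -1, -2, +1, +2 over states
    NS, CS1, CS2, LS1, LS2, clipped to [0.01, 0.99] and recorded in truth.
    """
    base = base_spec if base_spec is not None else silk_spec(mixture_w=0.5)
    if base.kind != "birefringent_cylinder":
        raise ValueError("stretch_series requires a birefringent_cylinder spec")
    steps = {"NS": 0, "CS1": -1, "CS2": -2, "LS1": +1, "LS2": +2}
    out = []
    for i, state in enumerate(STRETCH_STATES):
        w = float(np.clip(base.mixture_w + steps[state] * delta_w, 0.01, 0.99))
        spec = replace(base, mixture_w=w)
        image, truth = generate_phantom([spec], shape=shape, seed=seed + i)
        truth.meta.update({"state": state, "scheduled_w": w})
        out.append((state, image, truth))
    return out
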