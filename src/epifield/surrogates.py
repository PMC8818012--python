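"""Surrogate cortical surfaces, electrodes, and synthetic reference recordings.

Patient cortical geometry cannot be redistributed, so every downstream
stage is exercised on constructed surfaces instead: a flat rectangular
sheet, a sinusoidally folded sheet, and a seeded random-gyral sheet.
All three share the same planform footprint, sized to a 9-contact depth
electrode: the sheet extends ``m`` mm beyond both ends of the electrode
span ``l`` and ``m`` to both sides, i.e. (l + 2m) x 2m, with l = 28 mm
(first-to-last contact distance at 3.5 mm pitch) and m = 15 mm by
default.  The flat sheet sits ``standoff`` = 1.47 mm from the electrode
axis; the folded sheets oscillate around the electrode plane.

A synthetic "observed" SEEG recording is produced by running the full
simulate -> project -> bipolar chain on a chosen surrogate and adding
seeded Gaussian sensor noise; it stands in for a clinical recording in
the surface-comparison experiment and is tagged with the identity of
the generating surface so identifiability can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .epileptor import EpileptorParams, build_local_kernel, simulate_field
from .mesh import Electrode, TriSurface, geodesic_distances

__all__ = [
    "SurrogateSpec",
    "ExcitabilityMap",
    "make_electrode",
    "make_flat_surrogate",
    "make_sine_surrogate",
    "make_gyral_surrogate",
    "make_surrogate",
    "make_excitability_map",
    "make_reference_recording",
    "nearest_vertex",
    "grid_sheet",
]


@dataclass
class SurrogateSpec:
    """Geometry of a surrogate sheet.

    ``l`` is the electrode span (mm), ``m`` the margin beyond the
    electrode on every side, ``amplitude`` the fold amplitude of the
    sine sheet, ``standoff`` the flat-sheet-to-electrode distance, and
    ``target_edge_length`` the grid resolution.  ``seed`` (gyral only)
    makes the random folds reproducible.
    """

    kind: str = "flat"
    l: float = 28.0
    m: float = 15.0
    amplitude: float = 7.89
    standoff: float = 1.47
    target_edge_length: float = 0.4
    seed: int | None = None
    fold_wavelength: float = 25.0
    fold_amplitude: float = 8.0

    def __post_init__(self):
        if self.l <= 0 or self.m <= 0:
            raise ValueError("l and m must be positive")
        if self.amplitude < 0 or self.standoff < 0:
            raise ValueError("amplitude and standoff must be non-negative")


@dataclass
class ExcitabilityMap:
    """Per-vertex excitability field u0(x) with the epileptogenic-zone mask."""

    values: np.ndarray
    ez_vertex_mask: np.ndarray


def make_electrode(
    n_contacts: int = 9,
    pitch: float = 3.5,
    origin=(0.0, 0.0, 0.0),
    direction=(1.0, 0.0, 0.0),
) -> Electrode:
    """Linear depth electrode: contacts at origin + k * pitch * direction.

    Contacts are named "c1".."cn" from the innermost (mesial) end.
    """
    if n_contacts < 2:
        raise ValueError("at least two contacts required")
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("direction must be a non-zero vector")
    direction = direction / norm
    origin = np.asarray(origin, dtype=float)
    k = np.arange(n_contacts)[:, None]
    pos = origin[None, :] + k * pitch * direction[None, :]
    names = [f"c{i + 1}" for i in range(n_contacts)]
    return Electrode(pos, names, pitch=pitch)


def grid_sheet(lx: float, ly: float, edge_length: float, height=None) -> TriSurface:
    """Regular triangulated sheet over [0, lx] x [0, ly].

    Cell diagonals alternate in a checkerboard pattern for isotropy.
    ``height(x, y)`` optionally supplies the z coordinate.  Triangles
    wind counter-clockwise seen from +z.
    """
    nx = max(1, int(round(lx / edge_length)))
    ny = max(1, int(round(ly / edge_length)))
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = height(X, Y) if height is not None else np.zeros_like(X)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    i, j = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    a = (i * (ny + 1) + j).ravel()
    b = ((i + 1) * (ny + 1) + j).ravel()
    c = ((i + 1) * (ny + 1) + j + 1).ravel()
    d = (i * (ny + 1) + j + 1).ravel()
    even = ((i + j) % 2 == 0).ravel()
    t1 = np.where(even[:, None], np.column_stack([a, b, c]), np.column_stack([a, b, d]))
    t2 = np.where(even[:, None], np.column_stack([a, c, d]), np.column_stack([b, c, d]))
    return TriSurface(verts, np.vstack([t1, t2]))


def _check_resolution(spec: SurrogateSpec):
    if spec.target_edge_length > spec.m:
        raise ValueError("target_edge_length exceeds the margin m; mesh would be degenerate")


def _electrode_for(spec: SurrogateSpec, z: float) -> Electrode:
    n = int(round(spec.l / 3.5)) + 1
    return make_electrode(
        n_contacts=n, pitch=spec.l / (n - 1),
        origin=(spec.m, spec.m, z), direction=(1.0, 0.0, 0.0),
    )


def make_flat_surrogate(spec: SurrogateSpec | None = None) -> tuple[TriSurface, Electrode]:
    """Flat rectangular sheet with the electrode ``standoff`` mm above it.

    The sheet spans (l + 2m) x 2m exactly in the z = 0 plane; the
    electrode runs parallel to the long side through the transverse
    centre, contacts covering the central l mm.
    """
    spec = spec or SurrogateSpec(kind="flat")
    _check_resolution(spec)
    surf = grid_sheet(spec.l + 2 * spec.m, 2 * spec.m, spec.target_edge_length)
    return surf, _electrode_for(spec, spec.standoff)


def make_sine_surrogate(spec: SurrogateSpec | None = None) -> tuple[TriSurface, Electrode]:
    """Sinusoidally folded sheet; the electrode threads the folds at z = 0.

    The height field is z = A sin(2 pi (x - x0) / l) over the same
    (l + 2m) x 2m footprint as the flat sheet, with wavelength equal to
    the electrode span and the phase chosen so no contact sits at a
    zero crossing (contacts are offset half a pitch from the nodes,
    keeping the closest approach of surface to contact above 3 mm for
    the default amplitude).
    """
    spec = spec or SurrogateSpec(kind="sine")
    _check_resolution(spec)
    x0 = spec.m + 1.75  # half a contact pitch past the first contact
    A, l = spec.amplitude, spec.l

    def height(x, y):
        return A * np.sin(2 * np.pi * (x - x0) / l)

    surf = grid_sheet(spec.l + 2 * spec.m, 2 * spec.m, spec.target_edge_length, height)
    return surf, _electrode_for(spec, 0.0)


def make_gyral_surrogate(spec: SurrogateSpec) -> tuple[TriSurface, Electrode]:
    """Randomly folded sheet: a seeded band-limited Gaussian height field.

    White noise on the grid is smoothed with a Gaussian of scale
    ``fold_wavelength / 4`` and rescaled so the folds have an RMS height
    of ``fold_amplitude / 2`` (peaks near +-fold_amplitude), emulating
    gyral/sulcal undulation around the electrode plane.  Deterministic
    for a fixed seed.
    """
    if spec.seed is None:
        raise ValueError("gyral surrogate requires a seed")
    _check_resolution(spec)
    h = spec.target_edge_length
    nx = max(1, int(round((spec.l + 2 * spec.m) / h)))
    ny = max(1, int(round(2 * spec.m / h)))
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((nx + 1, ny + 1))
    sigma = (spec.fold_wavelength / 4.0) / h
    smooth = ndimage.gaussian_filter(noise, sigma, mode="reflect")
    sd = smooth.std()
    if sd > 0 and spec.fold_amplitude > 0:
        smooth = smooth * (spec.fold_amplitude / 2.0) / sd
    else:
        smooth = np.zeros_like(smooth)
    smooth -= smooth.mean()

    def height(x, y):
        ix = np.clip(np.round(x / h).astype(int), 0, nx)
        iy = np.clip(np.round(y / h).astype(int), 0, ny)
        return smooth[ix, iy]

    surf = grid_sheet(spec.l + 2 * spec.m, 2 * spec.m, h, height)
    return surf, _electrode_for(spec, spec.standoff)


def make_surrogate(spec: SurrogateSpec) -> tuple[TriSurface, Electrode]:
    """Dispatch on ``spec.kind`` ('flat' | 'sine' | 'gyral')."""
    if spec.kind == "flat":
        return make_flat_surrogate(spec)
    if spec.kind == "sine":
        return make_sine_surrogate(spec)
    if spec.kind == "gyral":
        return make_gyral_surrogate(spec)
    raise ValueError(f"unknown surrogate kind {spec.kind!r}")


def nearest_vertex(surface: TriSurface, point) -> int:
    """Index of the mesh vertex closest to a point in space."""
    return int(np.argmin(np.linalg.norm(surface.vertices - np.asarray(point, float), axis=1)))


def make_excitability_map(
    surface: TriSurface,
    ez_center: int | None = None,
    ez_diameter: float = 5.0,
    u0_ez: float = -1.8,
    u0_surround: float = -2.3,
) -> ExcitabilityMap:
    """Excitability field: a supercritical geodesic disc in bistable tissue.

    Vertices within ``ez_diameter / 2`` (geodesic) of ``ez_center``
    receive ``u0_ez``; everything else ``u0_surround``.  Without a
    centre the map is uniformly subcritical.
    """
    values = np.full(surface.n_vertices, u0_surround, dtype=float)
    mask = np.zeros(surface.n_vertices, dtype=bool)
    if ez_center is not None:
        gf = geodesic_distances(surface, ez_center, cutoff=max(ez_diameter, 1.0))
        mask = gf.distances <= ez_diameter / 2.0
        if mask.sum() < 3:
            raise ValueError(
                "epileptogenic zone covers fewer than 3 vertices; "
                "refine the mesh (triangle_quadrisect) or enlarge ez_diameter"
            )
        values[mask] = u0_ez
    return ExcitabilityMap(values, mask)


def make_reference_recording(
    spec: SurrogateSpec,
    params: EpileptorParams | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration: float = 20.0,
    output_rate: float = 256.0,
    ez_diameter: float = 5.0,
):
    """Synthetic "observed" SEEG recording from a named surrogate surface.

    Runs the full chain -- surface generation, local kernel, field
    simulation with the epileptogenic zone next to the innermost
    contact, dipole projection, bipolar referencing -- and adds seeded
    Gaussian observation noise of standard deviation ``noise_sd`` (in
    signal units).  The output is tagged with the generating surface
    kind so identifiability experiments can score the ranking.
    """
    from .forward import bipolar_reference, compute_gain_matrix, project_to_sensors

    params = params or EpileptorParams()
    surface, electrode = make_surrogate(spec)
    ez = nearest_vertex(surface, electrode.contact_positions[0])
    u0map = make_excitability_map(
        surface, ez, ez_diameter=ez_diameter,
        u0_ez=params.u0_ez, u0_surround=params.u0_surround,
    )
    kernel = build_local_kernel(surface, b=params.b)
    result = simulate_field(
        surface, params, u0map, duration, output_rate=output_rate, kernel=kernel
    )
    gain = compute_gain_matrix(surface, electrode)
    signals = bipolar_reference(project_to_sensors(gain, result))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signals.signals = signals.signals + rng.normal(
            0.0, noise_sd, size=signals.signals.shape
        )
    signals.meta.update(
        {"generating_surface": spec.kind, "noise_sd": noise_sd, "seed": seed}
    )
    return signals
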