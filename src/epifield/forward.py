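"""Dipole forward model from the cortical source sheet to SEEG sensors.

Pyramidal cells orient their dendrites perpendicular to the cortical
surface, so each patch of cortex is treated as a current dipole along
the local outward normal.  The potential a contact at x_s picks up from
the discretised sheet is

    phi(x_s, t) = sum_v A_v * n_v . (x_s - x_v) / |x_s - x_v|^3 * s_v(t),

a plain dipole kernel without conductivity prefactors: every amplitude
in this package is relative, which is all the bipolar-montage analyses
need.  The time-independent part is the gain (lead-field) matrix G, so
sensor signals are phi(t) = G s(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epileptor import SimulationResult
from .mesh import Electrode, TriSurface

__all__ = [
    "GainMatrix",
    "SensorSignals",
    "compute_gain_matrix",
    "project_to_sensors",
    "bipolar_reference",
    "gain_selectivity",
    "homogeneous_amplitude_proxy",
]


@dataclass
class GainMatrix:
    """Lead field G (n_sensors x n_vertices) with channel names."""

    matrix: np.ndarray
    sensor_names: list[str]
    referencing: str = "monopolar"

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SensorSignals:
    """Sensor time series (n_times x n_channels) at a fixed sampling rate."""

    signals: np.ndarray
    channel_names: list[str]
    fs: float
    referencing: str = "monopolar"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")


def compute_gain_matrix(surface: TriSurface, electrode: Electrode) -> GainMatrix:
    """Dipole gain matrix G[s, v] = A_v n_v . (x_s - x_v) / |x_s - x_v|^3."""
    diff = electrode.contact_positions[:, None, :] - surface.vertices[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    if r.min() <= 1e-6:
        s, v = np.unravel_index(np.argmin(r), r.shape)
        raise ValueError(
            f"contact {electrode.contact_names[s]} coincides with vertex {v} "
            "(dipole kernel singular)"
        )
    proj = np.einsum("svk,vk->sv", diff, surface.vertex_normals)
    G = surface.vertex_areas[None, :] * proj / r**3
    return GainMatrix(G, list(electrode.contact_names), "monopolar")


def project_to_sensors(G: GainMatrix, result: SimulationResult) -> SensorSignals:
    """Project source activity through the gain matrix: phi(t) = G s(t)."""
    if result.s.shape[1] != G.matrix.shape[1]:
        raise ValueError(
            f"gain matrix covers {G.matrix.shape[1]} vertices but the simulation "
            f"has {result.s.shape[1]}"
        )
    signals = result.s @ G.matrix.T
    return SensorSignals(signals, list(G.sensor_names), result.fs, G.referencing)


def _bipolar_names(names: list[str]) -> list[str]:
    return [f"{b}-{a}" for a, b in zip(names[:-1], names[1:])]


def bipolar_reference(obj):
    """Difference neighbouring contacts: channel k = contact(k+1) - contact(k).

    Accepts a :class:`GainMatrix` (returns the bipolar gain rows) or a
    :class:`SensorSignals` (returns the bipolar traces); n contacts give
    n - 1 channels named like "c2-c1".
    """
    if isinstance(obj, GainMatrix):
        if obj.n_sensors < 2:
            raise ValueError("bipolar referencing needs at least two channels")
        return GainMatrix(
            np.diff(obj.matrix, axis=0), _bipolar_names(obj.sensor_names), "bipolar"
        )
    if isinstance(obj, SensorSignals):
        if obj.signals.shape[1] < 2:
            raise ValueError("bipolar referencing needs at least two channels")
        return SensorSignals(
            np.diff(obj.signals, axis=1),
            _bipolar_names(obj.channel_names),
            obj.fs,
            "bipolar",
            dict(obj.meta),
        )
    raise TypeError("expected a GainMatrix or SensorSignals")


def gain_selectivity(
    G: GainMatrix, vertex_areas: np.ndarray, fraction: float = 0.5
):
    """Cortical area accounting for a fraction of the accumulated |gain|.

    For every channel the vertices are sorted by decreasing absolute
    gain and both |gain| and vertex area are accumulated; the returned
    ``area_at_fraction[c]`` is the accumulated area (mm^2) at which the
    accumulated |gain| first reaches ``fraction`` of the channel total,
    interpolated linearly between the bracketing vertices.  Channels
    with an all-zero row yield NaN.

    Returns ``(area_at_fraction, curves)`` where ``curves`` is a list of
    ``(cum_area, cum_gain_fraction)`` pairs per channel.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    areas_out = np.empty(G.n_sensors)
    curves = []
    for c in range(G.n_sensors):
        g = np.abs(G.matrix[c])
        total = g.sum()
        order = np.argsort(g)[::-1]
        cg = np.cumsum(g[order])
        ca = np.cumsum(vertex_areas[order])
        if total == 0:
            areas_out[c] = np.nan
            curves.append((ca, np.zeros_like(cg)))
            continue
        frac_curve = cg / total
        curves.append((ca, frac_curve))
        areas_out[c] = float(
            np.interp(fraction, np.concatenate([[0.0], frac_curve]),
                      np.concatenate([[0.0], ca]))
        )
    return areas_out, curves


def homogeneous_amplitude_proxy(G: GainMatrix) -> np.ndarray:
    """Geometry-only bipolar amplitude proxy g_bar(i+1, i) = |sum_j G[i+1,j] - G[i,j]|.

    For spatially homogeneous source dynamics the bipolar signal on the
    pair (i+1, i) is exactly proportional to this number, so comparing
    it to simulated envelope means reveals how much of the amplitude
    profile is pure geometry.
    """
    if G.referencing != "monopolar":
        raise ValueError("expects the monopolar gain matrix")
    if G.n_sensors < 2:
        raise ValueError("needs at least two contacts")
    row_sums = G.matrix.sum(axis=1)
    return np.abs(np.diff(row_sums))
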