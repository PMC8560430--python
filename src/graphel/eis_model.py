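"""Forward model of the graphene electrode/electrolyte equivalent circuit.

The interface of a graphene microelectrode in saline is modelled by a
Randles-type circuit with a graphene-specific twist: the Helmholtz
double layer is a constant phase element (CPE) and, because graphene's
low density of states adds a quantum capacitance ``C_q`` in series with
the double layer, the capacitive branch is ``CPE — C_q``.  The faradaic
branch is a charge-transfer resistance ``R_ct`` in series with a bounded
Warburg diffusion element.  The two branches are in parallel, behind the
solution series resistance ``R_s``::

            ┌── CPE(Q_dl, α) ── C_q ──┐
    R_s ────┤                         ├────
            └── R_ct ──── W_b(W, B) ──┘

Element impedances (ω = 2πf, principal complex branch everywhere):

* CPE:              Z = 1 / (Q (jω)^α)
* ideal capacitor:  Z = 1 / (jωC)
* bounded Warburg:  Z = W · tanh(B √(jω)) / √(jω)

``Q_dl`` and the absolute quantum capacitance are obtained from the
specific (per-area) values by multiplying with the geometric electrode
area and the AFM-derived roughness factor (effective/geometric surface
area, ≥ 1).  The circuit topology is configurable via
:func:`z_circuit`'s ``topology`` argument so alternative wirings can be
swapped in without touching the element functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import numpy.typing as npt

__all__ = [
    "CircuitParameters",
    "ImpedanceSpectrum",
    "HeightMap",
    "default_grid",
    "z_cpe",
    "z_capacitor",
    "z_bounded_warburg",
    "z_circuit",
    "randles_quantum_topology",
    "simulate_spectrum",
    "effective_area_ratio",
    "load_parameters",
    "preset_parameters",
]

# Intan-style acquisition requires 1 kHz impedance below this for a
# usable signal-to-noise ratio; shared with graphel.longitudinal.
WORKING_THRESHOLD_OHM = 2e6


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)) or np.any(np.asarray(value) <= 0):
            raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class CircuitParameters:
    """Equivalent-circuit parameters for one electrode.

    Parameters
    ----------
    r_s : float
        Solution series resistance, Ω.
    c_dl_specific : float
        Double-layer CPE magnitude per area, µF cm⁻².
    alpha : float
        CPE exponent in (0, 1]; 1 recovers an ideal capacitor.
    c_q_specific : float
        Graphene quantum capacitance per area, µF cm⁻².
    r_ct : float
        Charge-transfer resistance, Ω.
    w_mag : float
        Bounded-Warburg magnitude, Ω s⁻¹ᐟ².
    b : float
        Bounded-Warburg time parameter, s¹ᐟ² (the argument of tanh is
        ``b·√ω``, dimensionless).
    area_cm2 : float
        Geometric electrode area, cm².
    roughness : float
        Effective/geometric surface-area ratio from AFM, ≥ 1.
    """

    r_s: float
    c_dl_specific: float
    alpha: float
    c_q_specific: float
    r_ct: float
    w_mag: float
    b: float
    area_cm2: float = 1e-4
    roughness: float = 1.0

    def __post_init__(self) -> None:
        _check_positive(
            r_s=self.r_s,
            c_dl_specific=self.c_dl_specific,
            c_q_specific=self.c_q_specific,
            r_ct=self.r_ct,
            w_mag=self.w_mag,
            b=self.b,
            area_cm2=self.area_cm2,
        )
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.roughness < 1:
            raise ValueError(f"roughness must be >= 1, got {self.roughness}")

    @property
    def q_dl(self) -> float:
        """Absolute CPE magnitude, F·s^(α−1)."""
        return self.c_dl_specific * 1e-6 * self.area_cm2 * self.roughness

    @property
    def c_q(self) -> float:
        """Absolute quantum capacitance, F."""
        return self.c_q_specific * 1e-6 * self.area_cm2 * self.roughness

    def replace(self, **changes: float) -> "CircuitParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {
            "r_s_ohm": self.r_s,
            "c_dl_uF_per_cm2": self.c_dl_specific,
            "alpha": self.alpha,
            "c_q_uF_per_cm2": self.c_q_specific,
            "r_ct_ohm": self.r_ct,
            "w_mag_ohm_s_neg_half": self.w_mag,
            "b_s_half": self.b,
            "area_cm2": self.area_cm2,
            "roughness": self.roughness,
        }

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "CircuitParameters":
        return cls(
            r_s=d["r_s_ohm"],
            c_dl_specific=d["c_dl_uF_per_cm2"],
            alpha=d["alpha"],
            c_q_specific=d["c_q_uF_per_cm2"],
            r_ct=d["r_ct_ohm"],
            w_mag=d["w_mag_ohm_s_neg_half"],
            b=d["b_s_half"],
            area_cm2=d["area_cm2"],
            roughness=d["roughness"],
        )


def default_grid(f_min: float = 1.0, f_max: float = 1e5, n: int = 50) -> npt.NDArray[np.float64]:
    """Log-spaced frequency grid, default 1 Hz – 100 kHz, 50 points."""
    _check_positive(f_min=f_min, f_max=f_max)
    if n < 1 or f_max <= f_min:
        raise ValueError("need n >= 1 and f_max > f_min")
    return np.logspace(np.log10(f_min), np.log10(f_max), n)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance sampled on a strictly increasing frequency grid."""

    frequencies: npt.NDArray[np.float64]
    z: npt.NDArray[np.complex128]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        z = np.asarray(self.z, dtype=complex)
        if f.size == 0:
            raise ValueError("spectrum must be non-empty")
        if f.shape != z.shape:
            raise ValueError("frequencies and z must have equal length")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly positive and increasing")
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(z))):
            raise ValueError("spectrum contains non-finite values")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "z", z)

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def magnitude(self) -> npt.NDArray[np.float64]:
        return np.abs(self.z)

    @property
    def phase_deg(self) -> npt.NDArray[np.float64]:
        return np.degrees(np.angle(self.z))


@dataclass(frozen=True)
class HeightMap:
    """AFM-style surface height map with physical pixel sizes (µm)."""

    heights: npt.NDArray[np.float64]
    pixel_x: float
    pixel_y: float

    def __post_init__(self) -> None:
        h = np.atleast_2d(np.asarray(self.heights, dtype=float))
        if not np.all(np.isfinite(h)):
            raise ValueError("height map contains non-finite values")
        _check_positive(pixel_x=self.pixel_x, pixel_y=self.pixel_y)
        object.__setattr__(self, "heights", h)


def _omega(freq):
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        raise ValueError("frequency must be strictly positive and finite")
    return 2.0 * np.pi * f


def z_cpe(q_abs: float, alpha: float, freq) -> np.complex128:
    """Constant-phase-element impedance ``1 / (Q (jω)^α)``.

    Phase is −α·90° at every frequency; α = 1 recovers an ideal
    capacitor of capacitance ``q_abs``.
    """
    _check_positive(q_abs=q_abs)
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    w = _omega(freq)
    return 1.0 / (q_abs * (1j * w) ** alpha)


def z_capacitor(c: float, freq) -> np.complex128:
    """Ideal capacitor impedance ``1 / (jωC)`` (purely imaginary, < 0)."""
    _check_positive(c=c)
    return 1.0 / (1j * _omega(freq) * c)


def z_bounded_warburg(w_mag: float, b: float, freq) -> np.complex128:
    """Bounded (finite-length) Warburg impedance ``W·tanh(B√(jω))/√(jω)``.

    Limits: for ω → 0 the element is resistive with value ``W·B``; for
    ``B√ω`` large it approaches the semi-infinite Warburg ``W/√(jω)``
    with a −45° phase.  The principal complex square root is used, and
    tanh saturates to 1 for large arguments to avoid overflow.
    """
    _check_positive(w_mag=w_mag, b=b)
    s = np.sqrt(1j * _omega(freq))
    x = b * s
    # ctanh overflows/loses accuracy for huge |Re x|; it is 1 to double
    # precision once Re x > 20.
    t = np.where(np.real(x) > 20.0, 1.0 + 0.0j, np.tanh(np.where(np.real(x) > 20.0, 0, x)))
    return w_mag * t / s


def randles_quantum_topology(params: CircuitParameters, freq) -> np.complex128:
    """Default wiring: R_s + [ (CPE_dl — C_q)  ∥  (R_ct — W_b) ]."""
    z_cap_branch = z_cpe(params.q_dl, params.alpha, freq) + z_capacitor(params.c_q, freq)
    z_far_branch = params.r_ct + z_bounded_warburg(params.w_mag, params.b, freq)
    return params.r_s + (z_cap_branch * z_far_branch) / (z_cap_branch + z_far_branch)


def z_circuit(
    params: CircuitParameters,
    freq,
    topology: Callable[[CircuitParameters, object], np.complex128] = randles_quantum_topology,
) -> np.complex128:
    """Total circuit impedance at ``freq`` (Hz, scalar or array).

    The high-frequency limit is ``r_s`` (all interfacial branches
    vanish); the low-frequency limit of the real part is
    ``r_s + r_ct + w_mag·b`` (capacitive branch open, tanh linearized).
    """
    return topology(params, freq)


def simulate_spectrum(
    params: CircuitParameters,
    frequencies=None,
    topology: Callable = randles_quantum_topology,
) -> ImpedanceSpectrum:
    """Deterministic forward simulation of the circuit on a grid."""
    if frequencies is None:
        frequencies = default_grid()
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if f.size == 0:
        raise ValueError("frequency grid is empty")
    return ImpedanceSpectrum(f, z_circuit(params, f, topology=topology))


def effective_area_ratio(height_map: HeightMap) -> float:
    """Effective/geometric surface-area ratio from an AFM height map.

    Each pixel cell is split into two triangles whose 3-D areas are
    summed and divided by the projected (flat) area.  Returns exactly
    1.0 for a flat map and ``1/cos θ`` for a plane tilted by θ; the
    ratio is invariant under uniform lateral+vertical rescaling.
    """
    h = height_map.heights
    if h.shape[0] < 2 or h.shape[1] < 2:
        raise ValueError("height map must be at least 2x2")
    dx, dy = height_map.pixel_x, height_map.pixel_y

    # Corner heights of each cell.
    h00 = h[:-1, :-1]
    h01 = h[:-1, 1:]
    h10 = h[1:, :-1]
    h11 = h[1:, 1:]

    def tri_area(p, q, r):
        # p, q, r: tuples of (x, y, z) component arrays
        ux, uy, uz = q[0] - p[0], q[1] - p[1], q[2] - p[2]
        vx, vy, vz = r[0] - p[0], r[1] - p[1], r[2] - p[2]
        cx = uy * vz - uz * vy
        cy = uz * vx - ux * vz
        cz = ux * vy - uy * vx
        return 0.5 * np.sqrt(cx**2 + cy**2 + cz**2)

    zero = np.zeros_like(h00)
    p00 = (zero, zero, h00)
    p01 = (zero + dx, zero, h01)
    p10 = (zero, zero + dy, h10)
    p11 = (zero + dx, zero + dy, h11)
    area3d = np.sum(tri_area(p00, p01, p10) + tri_area(p11, p01, p10))
    area2d = dx * dy * h00.size
    return float(area3d / area2d)


# ---------------------------------------------------------------------------
# Packaged representative parameter sets
# ---------------------------------------------------------------------------

_PRESET_FILES = {"PET": "circuit_pet.json", "SU-8": "circuit_su8.json"}


def load_parameters(path) -> CircuitParameters:
    """Load circuit parameters from a JSON file (keys as in ``to_dict``)."""
    with open(path, "r", encoding="utf-8") as fh:
        return CircuitParameters.from_dict(json.load(fh))


def preset_parameters(substrate: str) -> CircuitParameters:
    """Representative fitted parameters for a substrate ("PET" or "SU-8").

    These are the packaged reference values for graphene
    microelectrodes on each substrate (100 µm × 100 µm site, roughness
    from AFM: +1.5% for PET, +7% for SU-8).
    """
    key = substrate.upper().replace("SU8", "SU-8")
    if key not in _PRESET_FILES:
        raise KeyError(f"unknown substrate {substrate!r}; choose from {sorted(_PRESET_FILES)}")
    ref = resources.files("graphel.data").joinpath(_PRESET_FILES[key])
    return CircuitParameters.from_dict(json.loads(ref.read_text(encoding="utf-8")))
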