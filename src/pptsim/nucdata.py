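"""Materials, photon attenuation coefficients, positron stopping data and
the lead-212 decay-chain emission spectrum.

All interaction data are embedded (see :mod:`pptsim.tables`); nothing is
downloaded.  Photon coefficients are tabulated per interaction channel
(photoelectric, Compton, pair production) as *linear* coefficients in
cm^-1 on a 0.05-3 MeV grid and interpolated log-log in energy.  The pair
channel is identically zero below the 2 m_e c^2 = 1.022 MeV threshold and
includes triplet production.  Positron continuous-slowing-down (CSDA)
ranges are stored as mass ranges (g/cm^2) and converted to lengths with
the material density; cortical bone carries its own stopping table, the
soft tissues share the water curve (their compositions are close to
water, so the mass range is nearly material-independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import tables

__all__ = [
    "Material",
    "EmissionSpectrum",
    "MATERIALS",
    "PB212_SPECTRUM",
    "PAIR_THRESHOLD_MEV",
    "get_material",
    "register_material",
    "get_coefficients",
    "mean_free_path",
    "csda_range",
    "materials_to_yaml",
    "materials_from_yaml",
]

PAIR_THRESHOLD_MEV = tables.PAIR_THRESHOLD_MEV
ENERGY_MIN_MEV = float(tables.ENERGY_GRID_MEV[0])
ENERGY_MAX_MEV = float(tables.ENERGY_GRID_MEV[-1])

CHANNELS = ("photoelectric", "compton", "pair")


@dataclass(frozen=True)
class Material:
    """A homogeneous material with photon and positron interaction data.

    Attributes
    ----------
    name : str
        Registry label, e.g. ``"water"``.
    density : float
        Mass density in g/cm^3.
    energies : ndarray
        Photon energy grid in MeV, strictly increasing.
    mu_photoelectric, mu_compton, mu_pair : ndarray
        Linear attenuation coefficients in cm^-1 on ``energies``.
    csda_ke : ndarray
        Positron kinetic energies (MeV) of the stopping table.
    csda_cm : ndarray
        CSDA range in cm at ``csda_ke`` (mass range / density).
    x0_g_cm2 : float
        Radiation length in g/cm^2 (multiple-scattering strength).
    """

    name: str
    density: float
    energies: np.ndarray
    mu_photoelectric: np.ndarray
    mu_compton: np.ndarray
    mu_pair: np.ndarray
    csda_ke: np.ndarray
    csda_cm: np.ndarray
    x0_g_cm2: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        e = np.asarray(self.energies, dtype=float)
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        for ch in (self.mu_photoelectric, self.mu_compton, self.mu_pair):
            if np.any(np.asarray(ch) < 0):
                raise ValueError("attenuation coefficients must be >= 0")
        if np.any(self.mu_pair[e < PAIR_THRESHOLD_MEV] != 0):
            raise ValueError("pair coefficient must be 0 below 1.022 MeV")
        if np.any(np.diff(np.asarray(self.csda_ke)) <= 0):
            raise ValueError("CSDA energy grid must be strictly increasing")
        if np.any(np.asarray(self.csda_cm) < 0):
            raise ValueError("CSDA ranges must be >= 0")

    @property
    def mu_total(self) -> np.ndarray:
        """Total linear attenuation coefficient on the energy grid."""
        return self.mu_photoelectric + self.mu_compton + self.mu_pair

    @property
    def x0_cm(self) -> float:
        """Radiation length in cm."""
        return self.x0_g_cm2 / self.density


def _loglog_interp(e, grid, values):
    """Log-log interpolation, exact at grid points; zeros handled linearly."""
    e = np.asarray(e, dtype=float)
    v = np.asarray(values, dtype=float)
    if np.all(v > 0):
        out = np.exp(np.interp(np.log(e), np.log(grid), np.log(v)))
    else:
        # pair channel: zero below threshold.  In the first segment with a
        # zero lower node, rise as (E - E_th)^3, the leading near-threshold
        # behaviour of the nuclear pair cross section.
        out = np.interp(e, grid, v)
        pos = v > 0
        if pos.any():
            k = int(np.argmax(pos))  # first positive node
            if k > 0:
                e_lo, e_hi, v_hi = grid[k - 1], grid[k], v[k]
                e_th = max(e_lo, PAIR_THRESHOLD_MEV)
                seg = (e > e_th) & (e < e_hi)
                frac = (e[seg] - e_th) / (e_hi - e_th)
                out = np.asarray(out, dtype=float)
                out[seg] = v_hi * frac**3
                out[e <= e_th] = 0.0
            if k + 1 < len(v):
                hi = e >= grid[k]
                out[hi] = np.exp(
                    np.interp(np.log(e[hi]), np.log(grid[k:]), np.log(v[k:]))
                )
    return out


def _check_energy(energy) -> np.ndarray:
    e = np.asarray(energy, dtype=float)
    if np.any(e < ENERGY_MIN_MEV) or np.any(e > ENERGY_MAX_MEV):
        raise ValueError(
            f"photon energy outside tabulated range "
            f"[{ENERGY_MIN_MEV}, {ENERGY_MAX_MEV}] MeV"
        )
    return e


def get_coefficients(material: Material | str, energy):
    """Per-channel linear attenuation coefficients at ``energy`` (MeV).

    Returns ``(mu_photoelectric, mu_compton, mu_pair)`` in cm^-1,
    interpolated log-log in energy.  ``energy`` may be a scalar or array;
    values outside the tabulated [0.05, 3.0] MeV range raise ``ValueError``.
    """
    m = get_material(material) if isinstance(material, str) else material
    e = _check_energy(energy)
    mu_pe = _loglog_interp(e, m.energies, m.mu_photoelectric)
    mu_c = _loglog_interp(e, m.energies, m.mu_compton)
    mu_pp = _loglog_interp(e, m.energies, m.mu_pair)
    mu_pp = np.where(e < PAIR_THRESHOLD_MEV, 0.0, mu_pp)
    if np.isscalar(energy) or np.ndim(energy) == 0:
        return float(mu_pe), float(mu_c), float(mu_pp)
    return mu_pe, mu_c, mu_pp


def mu_total(material: Material | str, energy):
    """Total linear attenuation coefficient (cm^-1) at ``energy`` MeV."""
    mu_pe, mu_c, mu_pp = get_coefficients(material, energy)
    return mu_pe + mu_c + mu_pp


def mean_free_path(material: Material | str, energy) -> float:
    """Photon mean free path 1/mu_total in cm at ``energy`` MeV."""
    return 1.0 / mu_total(material, energy)


def csda_range(material: Material | str, ke):
    """Positron CSDA range in cm at kinetic energy ``ke`` (MeV).

    Monotone increasing, zero at ke = 0.  Raises for negative energies or
    energies above the stopping table.
    """
    m = get_material(material) if isinstance(material, str) else material
    k = np.asarray(ke, dtype=float)
    if np.any(k < 0):
        raise ValueError("positron kinetic energy must be >= 0")
    if np.any(k > m.csda_ke[-1]):
        raise ValueError(
            f"kinetic energy above stopping table end ({m.csda_ke[-1]} MeV)"
        )
    r = np.interp(k, m.csda_ke, m.csda_cm)
    return float(r) if np.ndim(ke) == 0 else r


def ke_from_residual_range(material: Material | str, residual_cm):
    """Inverse stopping table: kinetic energy left after ``residual_cm``."""
    m = get_material(material) if isinstance(material, str) else material
    r = np.clip(np.asarray(residual_cm, dtype=float), 0.0, m.csda_cm[-1])
    return np.interp(r, m.csda_cm, m.csda_ke)


@dataclass(frozen=True)
class EmissionSpectrum:
    """Discrete gamma-line spectrum: (energy MeV, intensity/decay, nuclide)."""

    lines: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        for e, i, _ in self.lines:
            if e <= 0:
                raise ValueError("line energies must be positive")
            if not 0 <= i <= 1:
                raise ValueError("line intensities must be in [0, 1]")

    @property
    def energies(self) -> np.ndarray:
        return np.array([e for e, _, _ in self.lines])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i, _ in self.lines])

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` line energies with probability proportional to intensity."""
        p = self.intensities / self.intensities.sum()
        return rng.choice(self.energies, size=n, p=p)


def _build_default_materials() -> dict[str, Material]:
    out = {}
    for name, chans in tables.ATTENUATION_CM1.items():
        rho = tables.DENSITY_G_CM3[name]
        mass = tables.CSDA_BONE_GCM2 if name == "bone" else tables.CSDA_WATER_GCM2
        out[name] = Material(
            name=name,
            density=rho,
            energies=tables.ENERGY_GRID_MEV.copy(),
            mu_photoelectric=chans["photoelectric"].copy(),
            mu_compton=chans["compton"].copy(),
            mu_pair=chans["pair"].copy(),
            csda_ke=tables.CSDA_KE_MEV.copy(),
            csda_cm=mass / rho,
            x0_g_cm2=tables.X0_G_CM2[name],
        )
    return out


MATERIALS: dict[str, Material] = _build_default_materials()

PB212_SPECTRUM = EmissionSpectrum(lines=tuple(tables.PB212_CHAIN_LINES))


def get_material(name: str) -> Material:
    """Look up a registered material by name."""
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; registered: {sorted(MATERIALS)}"
        ) from None


def register_material(material: Material) -> None:
    """Add or replace a material in the registry (user overrides)."""
    MATERIALS[material.name] = material


def materials_to_yaml(path, materials: dict[str, Material] | None = None) -> None:
    """Serialize materials to a structured-text YAML file."""
    materials = MATERIALS if materials is None else materials
    doc = {}
    for name, m in materials.items():
        doc[name] = {
            "density_g_cm3": float(m.density),
            "energies_mev": [float(x) for x in m.energies],
            "mu_photoelectric_cm1": [float(x) for x in m.mu_photoelectric],
            "mu_compton_cm1": [float(x) for x in m.mu_compton],
            "mu_pair_cm1": [float(x) for x in m.mu_pair],
            "csda_ke_mev": [float(x) for x in m.csda_ke],
            "csda_range_cm": [float(x) for x in m.csda_cm],
            "x0_g_cm2": float(m.x0_g_cm2),
        }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=True)


def materials_from_yaml(path) -> dict[str, Material]:
    """Load materials from a YAML file written by :func:`materials_to_yaml`."""
    with open(path) as f:
        doc = yaml.safe_load(f)
    out = {}
    for name, d in doc.items():
        out[name] = Material(
            name=name,
            density=d["density_g_cm3"],
            energies=np.asarray(d["energies_mev"], dtype=float),
            mu_photoelectric=np.asarray(d["mu_photoelectric_cm1"], dtype=float),
            mu_compton=np.asarray(d["mu_compton_cm1"], dtype=float),
            mu_pair=np.asarray(d["mu_pair_cm1"], dtype=float),
            csda_ke=np.asarray(d["csda_ke_mev"], dtype=float),
            csda_cm=np.asarray(d["csda_range_cm"], dtype=float),
            x0_g_cm2=d["x0_g_cm2"],
        )
    return out
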