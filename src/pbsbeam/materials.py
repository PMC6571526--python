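"""Stoichiometric HU-to-material conversion and proton stopping powers.

The CT calibration starts from 12 core materials (10 body tissues expected
in a patient, plus aluminium and iron for implants) with known Hounsfield
unit, mass density, elemental composition and mean ionization energy.
Linear interpolation in HU produces 50 body materials and 5 Al/Fe metal
mixtures; a voxel is assigned the material closest in mass density, with
the voxel's interpolated density used to rescale the linear stopping power.

The core fixture below is implementer-supplied: densities, compositions and
I-values follow standard ICRU/ICRP tissue compilations; the HU anchors
(in particular for Al and Fe) are synthetic, chosen to give a realistic,
monotone HU-density curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import BETHE_K, ELECTRON_MASS_MEV, ELEMENTS, beta_gamma


@dataclass
class MaterialEntry:
    """One material of the HU calibration table.

    Mass fractions must sum to 1; ``hu_center`` is the average HU of the
    covered range and ``density_range`` the min/max density over the range,
    kept to correct the dE/dx for the actual voxel density.
    """

    name: str
    hu_center: float
    hu_range: tuple[float, float]
    density: float
    density_range: tuple[float, float]
    composition: dict[str, float]
    mean_ionization_energy: float  # eV
    category: str  # core | body | metal

    def __post_init__(self):
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total}, expected 1"
            )
        lo, hi = self.hu_range
        if not (lo <= self.hu_center <= hi):
            raise ValueError(f"hu_center of {self.name!r} outside hu_range")
        dlo, dhi = self.density_range
        if not (dlo - 1e-12 <= self.density <= dhi + 1e-12):
            raise ValueError(f"density of {self.name!r} outside density_range")

    @property
    def z_over_a(self) -> float:
        """Composition-weighted Z/A (mol/g)."""
        return sum(
            w * ELEMENTS[el][0] / ELEMENTS[el][1]
            for el, w in self.composition.items()
        )


@dataclass
class MaterialTable:
    """Ordered HU-partitioning list of materials (body segment then metals)."""

    entries: list[MaterialEntry]
    hu_domain: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("material table is empty")
        if self.hu_domain is None:
            self.hu_domain = (
                self.entries[0].hu_range[0],
                self.entries[-1].hu_range[1],
            )
        # the hu ranges must tile the domain without overlap
        for a, b in zip(self.entries, self.entries[1:]):
            if abs(a.hu_range[1] - b.hu_range[0]) > 1e-6:
                raise ValueError(
                    f"hu ranges of {a.name!r} and {b.name!r} do not tile"
                )

    @property
    def hu_centers(self) -> np.ndarray:
        return np.array([e.hu_center for e in self.entries])

    @property
    def densities(self) -> np.ndarray:
        return np.array([e.density for e in self.entries])


# --------------------------------------------------------------------------
# Core fixture (synthetic/implementer-supplied; see module docstring)
# --------------------------------------------------------------------------

def _norm(comp: dict[str, float]) -> dict[str, float]:
    s = sum(comp.values())
    return {k: v / s for k, v in comp.items()}


_CORE_SPECS = [
    # name, HU, density g/cc, I eV, composition (mass fractions, normalized)
    ("air", -1000.0, 0.001205, 85.7,
     {"C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012827}),
    ("lung", -740.0, 0.26, 75.3,
     {"H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749, "Na": 0.002,
      "P": 0.002, "S": 0.003, "Cl": 0.003, "K": 0.002}),
    ("adipose", -98.0, 0.95, 63.2,
     {"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278, "Na": 0.001,
      "S": 0.001, "Cl": 0.001}),
    ("water", 0.0, 1.0, 75.0, {"H": 0.111894, "O": 0.888106}),
    ("brain", 30.0, 1.04, 73.3,
     {"H": 0.107, "C": 0.145, "N": 0.022, "O": 0.712, "Na": 0.002,
      "P": 0.004, "S": 0.002, "Cl": 0.003, "K": 0.003}),
    ("muscle", 45.0, 1.05, 75.3,
     {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.710, "Na": 0.001,
      "P": 0.002, "S": 0.003, "Cl": 0.001, "K": 0.004}),
    ("liver", 60.0, 1.06, 74.7,
     {"H": 0.102, "C": 0.139, "N": 0.030, "O": 0.716, "Na": 0.002,
      "P": 0.003, "S": 0.003, "Cl": 0.002, "K": 0.003}),
    ("cartilage", 100.0, 1.10, 76.0,
     {"H": 0.096, "C": 0.099, "N": 0.022, "O": 0.744, "Na": 0.005,
      "P": 0.022, "S": 0.009, "Cl": 0.003}),
    ("trabecular_bone", 300.0, 1.18, 81.0,
     {"H": 0.085, "C": 0.404, "N": 0.058, "O": 0.367, "Na": 0.001,
      "Mg": 0.001, "P": 0.034, "S": 0.002, "Cl": 0.002, "K": 0.001,
      "Ca": 0.044, "Fe": 0.001}),
    ("cortical_bone", 1500.0, 1.92, 106.4,
     {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435, "Na": 0.001,
      "Mg": 0.002, "P": 0.103, "S": 0.003, "Ca": 0.225}),
    ("aluminium", 2700.0, 2.699, 166.0, {"Al": 1.0}),
    ("iron", 12000.0, 7.874, 286.0, {"Fe": 1.0}),
]


def core_materials() -> list[MaterialEntry]:
    """The bundled 12 core materials (10 body + Al + Fe), density-ordered."""
    out = []
    for name, hu, rho, i_ev, comp in _CORE_SPECS:
        out.append(
            MaterialEntry(
                name=name,
                hu_center=hu,
                hu_range=(hu, hu),
                density=rho,
                density_range=(rho, rho),
                composition=_norm(comp),
                mean_ionization_energy=i_ev,
                category="core",
            )
        )
    return out


# --------------------------------------------------------------------------
# Table construction
# --------------------------------------------------------------------------

def _interp_entry(a: MaterialEntry, b: MaterialEntry, hu: float,
                  name: str, category: str) -> MaterialEntry:
    """Linear interpolation of density, composition and I between two cores."""
    if b.hu_center == a.hu_center:
        t = 0.0
    else:
        t = (hu - a.hu_center) / (b.hu_center - a.hu_center)
    rho = (1 - t) * a.density + t * b.density
    i_ev = (1 - t) * a.mean_ionization_energy + t * b.mean_ionization_energy
    comp: dict[str, float] = {}
    for el in set(a.composition) | set(b.composition):
        w = (1 - t) * a.composition.get(el, 0.0) + t * b.composition.get(el, 0.0)
        if w > 0:
            comp[el] = w
    comp = _norm(comp)
    return MaterialEntry(
        name=name,
        hu_center=hu,
        hu_range=(hu, hu),  # assigned later
        density=rho,
        density_range=(rho, rho),  # assigned later
        composition=comp,
        mean_ionization_energy=i_ev,
        category=category,
    )


def _allocate_interior(gaps: np.ndarray, n_interior: int) -> list[int]:
    """Largest-remainder allocation of interior points to inter-core gaps."""
    quota = gaps / gaps.sum() * n_interior
    counts = np.floor(quota).astype(int)
    rem = n_interior - counts.sum()
    order = np.argsort(-(quota - counts))
    for i in order[:rem]:
        counts[i] += 1
    return list(counts)


def build_material_table(core: list[MaterialEntry] | None = None,
                         n_body: int = 50, n_metal: int = 5) -> MaterialTable:
    """Build the interpolated HU table from the 12 core materials.

    The body segment gets ``n_body`` materials: one at each of the 10 body
    core HUs plus interior points spread over the inter-core gaps in
    proportion to gap width.  The metal segment gets ``n_metal`` Al/Fe
    mixtures at equally spaced mixing fractions (endpoints included, so a
    query at the Al or Fe anchor returns the pure metal).
    """
    if core is None:
        core = core_materials()
    if len(core) != 12:
        raise ValueError(f"expected 12 core materials, got {len(core)}")
    body_cores, metals = core[:-2], core[-2:]
    dens = [m.density for m in core]
    if not all(a < b for a, b in zip(dens, dens[1:])):
        raise ValueError("core densities must be strictly increasing")
    if n_body < len(body_cores):
        raise ValueError("n_body smaller than number of body cores")
    if n_metal < 2:
        raise ValueError("need at least the two pure-metal endpoints")

    hu_cores = np.array([m.hu_center for m in body_cores])
    counts = _allocate_interior(np.diff(hu_cores), n_body - len(body_cores))

    entries: list[MaterialEntry] = []
    idx = 0
    for i, (a, b) in enumerate(zip(body_cores, body_cores[1:])):
        hus = np.linspace(a.hu_center, b.hu_center, counts[i] + 2)[:-1]
        for hu in hus:
            entries.append(_interp_entry(a, b, hu, f"body_{idx:02d}", "body"))
            idx += 1
    entries.append(
        _interp_entry(body_cores[-2], body_cores[-1],
                      body_cores[-1].hu_center, f"body_{idx:02d}", "body")
    )

    al, fe = metals
    for j in range(n_metal):
        t = j / (n_metal - 1)
        hu = (1 - t) * al.hu_center + t * fe.hu_center
        entries.append(_interp_entry(al, fe, hu, f"metal_{j}", "metal"))

    # assign tiling hu ranges at midpoints between consecutive centers
    centers = np.array([e.hu_center for e in entries])
    edges = np.concatenate(
        [[centers[0]], 0.5 * (centers[:-1] + centers[1:]), [centers[-1]]]
    )
    rhos = np.array([e.density for e in entries])
    for i, e in enumerate(entries):
        e.hu_range = (float(edges[i]), float(edges[i + 1]))
        lo = float(np.interp(edges[i], centers, rhos))
        hi = float(np.interp(edges[i + 1], centers, rhos))
        e.density_range = (min(lo, hi), max(lo, hi))
    return MaterialTable(entries=entries)


def hu_to_material(table: MaterialTable, hu: float) -> tuple[MaterialEntry, float]:
    """Map an HU value to (material entry, voxel density).

    The entry is the one whose HU range contains ``hu`` (equivalently the
    material closest in mass density along the piecewise-linear HU-density
    curve); the voxel density is read off that curve so the caller can
    rescale dE/dx.  Out-of-domain HUs are clamped with a warning.
    """
    lo, hi = table.hu_domain
    if hu < lo or hu > hi:
        warnings.warn(f"HU {hu} outside table domain [{lo}, {hi}]; clamped",
                      stacklevel=2)
        hu = min(max(hu, lo), hi)
    centers = table.hu_centers
    rho_vox = float(np.interp(hu, centers, table.densities))
    # hu ranges tile the domain; bisect on the upper edges
    uppers = np.array([e.hu_range[1] for e in table.entries])
    i = int(np.searchsorted(uppers, hu))
    i = min(i, len(table.entries) - 1)
    return table.entries[i], rho_vox


def stopping_power(material: MaterialEntry, kinetic_energy: float,
                   density_override: float | None = None,
                   density_effect: bool = False) -> float:
    """Proton linear stopping power dE/dx (MeV/cm) from the Bethe formula.

    Uses the composition-weighted Z/A and the material's mean ionization
    energy; shell and density-effect corrections are omitted by default
    (``density_effect=True`` adds a simple Sternheimer-asymptotic term).
    ``density_override`` rescales the result linearly (mass stopping power
    is composition-only).
    """
    e = float(kinetic_energy)
    if not (0.5 <= e <= 300.0):
        raise ValueError(f"kinetic energy {e} MeV outside validity range "
                         "[0.5, 300] MeV")
    rho = material.density if density_override is None else float(density_override)
    beta, gamma = beta_gamma(e)
    beta2 = float(beta) ** 2
    i_mev = material.mean_ionization_energy * 1e-6
    arg = 2.0 * ELECTRON_MASS_MEV * beta2 * gamma * gamma / i_mev
    bracket = np.log(arg) - beta2
    if density_effect:
        # asymptotic Sternheimer: delta/2 ~ ln(h nu_p / I) + ln(beta gamma) - 1/2
        hnu_p = 28.816e-6 * np.sqrt(rho * material.z_over_a) * 1e-6  # MeV
        delta_half = np.log(hnu_p / i_mev) + np.log(beta * gamma) - 0.5
        bracket -= max(0.0, float(delta_half))
    return float(BETHE_K * material.z_over_a * rho / beta2 * bracket)


WATER = core_materials()[3]


# --------------------------------------------------------------------------
# TSV export / import
# --------------------------------------------------------------------------

_TSV_ELEMENTS = list(ELEMENTS)


def write_material_table(table: MaterialTable, path) -> None:
    """Write the table as TSV: one row per material, element fractions last."""
    cols = ["name", "category", "hu_lo", "hu_hi", "hu_center", "density",
            "density_lo", "density_hi", "I_eV"] + _TSV_ELEMENTS
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in table.entries:
            row = [e.name, e.category,
                   repr(float(e.hu_range[0])), repr(float(e.hu_range[1])),
                   repr(float(e.hu_center)), repr(float(e.density)),
                   repr(float(e.density_range[0])),
                   repr(float(e.density_range[1])),
                   repr(float(e.mean_ionization_energy))]
            row += [repr(float(e.composition.get(el, 0.0)))
                    for el in _TSV_ELEMENTS]
            fh.write("\t".join(row) + "\n")


def read_material_table(path) -> MaterialTable:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    entries = []
    for _, r in df.iterrows():
        comp = {el: float(r[el]) for el in _TSV_ELEMENTS if float(r[el]) > 0}
        entries.append(MaterialEntry(
            name=str(r["name"]), category=str(r["category"]),
            hu_center=float(r["hu_center"]),
            hu_range=(float(r["hu_lo"]), float(r["hu_hi"])),
            density=float(r["density"]),
            density_range=(float(r["density_lo"]), float(r["density_hi"])),
            composition=comp, mean_ionization_energy=float(r["I_eV"]),
        ))
    return MaterialTable(entries=entries)
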