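"""Stoichiometric model of the secondary cell wall.

Converts bulk composition measurements (sugar molar ratios from
hydrolysate analysis, the carbohydrate:lignin mass ratio, moisture on a
dry basis) into per-microfibril residue counts, the 18-chain fibril
radius implied by crystal density, component volume fractions, and a
2D schematic bead layout around a Monte Carlo disk packing.

Conventions: one microfibril cross-section carries 18 glucan chains, so
counts are expressed per 18 glucose residues.  Anhydro-residue masses
are used for polymerised sugars (glucose 162, xylose/arabinose
132 g/mol); the lignin C9 monomer mass defaults to 211 g/mol, the mean
of syringyl and guaiacyl units for a 1:1 S:G wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .harddisk import DiskConfiguration

__all__ = [
    "SugarComposition",
    "MicrofibrilStoichiometry",
    "MONOMER_MASSES",
    "COMPONENT_DENSITIES",
    "AVOGADRO",
    "per_fibril_counts",
    "fibril_radius_from_chains",
    "molecular_volume",
    "volume_fractions",
    "conformer_allocation",
    "schematic_layout",
]

AVOGADRO = 6.02214076e23  # 1/mol

#: anhydro-residue / monomer masses, g/mol
MONOMER_MASSES: Dict[str, float] = {
    "glucose": 162.14,
    "xylose": 132.11,
    "arabinose": 132.11,
    "lignin": 211.0,
    "water": 18.02,
}

#: bulk densities, g/cm³ — package defaults, configurable
COMPONENT_DENSITIES: Dict[str, float] = {
    "cellulose": 1.6,
    "hemicellulose": 1.5,
    "lignin": 1.35,
    "water": 1.0,
}

CHAINS_PER_FIBRIL = 18


@dataclass(frozen=True)
class SugarComposition:
    """Molar parts of the wall sugars (scale-free)."""

    glucose: float
    xylose: float
    arabinose: float = 0.0

    def __post_init__(self) -> None:
        if self.glucose <= 0:
            raise ValueError("glucose part must be positive")
        if self.xylose < 0 or self.arabinose < 0:
            raise ValueError("sugar parts must be non-negative")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class MicrofibrilStoichiometry:
    """Residue counts per 18 glucose (one microfibril cross-section slab).

    Exact real-valued counts plus their presentation-style integers
    (half-up rounding).
    """

    xylose: float
    arabinose: float
    lignin: float
    water: float

    @property
    def rounded(self) -> Dict[str, int]:
        return {
            "glucose": CHAINS_PER_FIBRIL,
            "xylose": _round_half_up(self.xylose),
            "arabinose": _round_half_up(self.arabinose),
            "lignin": _round_half_up(self.lignin),
            "water": _round_half_up(self.water),
        }


def per_fibril_counts(
    sugars: SugarComposition,
    carb_to_lignin_mass: Tuple[float, float] = (65.0, 20.0),
    moisture_dry_basis: float = 0.30,
    monomer_masses: Mapping[str, float] = MONOMER_MASSES,
) -> MicrofibrilStoichiometry:
    """Residue counts per 18 glucose from bulk composition.

    Xylose/arabinose follow the sugar molar ratios directly; the lignin
    monomer count comes from the carbohydrate:lignin mass ratio applied
    to the carbohydrate mass of one 18-glucose slab; water molecules
    from the dry-basis moisture applied to the slab's dry
    (carbohydrate + lignin) mass.
    """
    carb_part, lignin_part = carb_to_lignin_mass
    if carb_part <= 0 or lignin_part < 0:
        raise ValueError("mass-ratio parts must be positive (lignin >= 0)")
    if moisture_dry_basis < 0:
        raise ValueError("moisture must be non-negative")
    m = monomer_masses
    n_xyl = CHAINS_PER_FIBRIL * sugars.xylose / sugars.glucose
    n_ara = CHAINS_PER_FIBRIL * sugars.arabinose / sugars.glucose
    carb_mass = (
        CHAINS_PER_FIBRIL * m["glucose"] + n_xyl * m["xylose"] + n_ara * m["arabinose"]
    )
    lignin_mass = carb_mass * lignin_part / carb_part
    n_lig = lignin_mass / m["lignin"]
    dry_mass = carb_mass + lignin_mass
    n_wat = moisture_dry_basis * dry_mass / m["water"]
    return MicrofibrilStoichiometry(
        xylose=n_xyl, arabinose=n_ara, lignin=n_lig, water=n_wat
    )


def fibril_radius_from_chains(
    n_chains: int = CHAINS_PER_FIBRIL,
    residue_mass: float = MONOMER_MASSES["glucose"],
    rise_per_residue: float = 5.19,
    density: float = COMPONENT_DENSITIES["cellulose"],
) -> float:
    """Equivalent cylinder radius (Å) of an n-chain crystalline fibril.

    One residue per chain occupies a slab of height ``rise_per_residue``
    (Å, half the cellulose I-beta c-axis repeat), so the cross-section
    area is n * m / (rise * density * N_A), converted to Å².
    """
    if n_chains <= 0 or residue_mass <= 0 or rise_per_residue <= 0 or density <= 0:
        raise ValueError("all fibril parameters must be positive")
    mass_g = n_chains * residue_mass / AVOGADRO
    volume_cm3 = mass_g / density
    volume_a3 = volume_cm3 * 1e24  # 1 cm³ = 1e24 Å³
    area = volume_a3 / rise_per_residue
    return float(np.sqrt(area / np.pi))


def molecular_volume(molar_mass: float = 18.02, density: float = 0.997) -> float:
    """Molecular volume in Å³ from molar mass (g/mol) and density (g/cm³)."""
    if molar_mass <= 0 or density <= 0:
        raise ValueError("mass and density must be positive")
    return molar_mass / (density * AVOGADRO) * 1e24


def volume_fractions(
    mass_comp: Mapping[str, float],
    densities: Mapping[str, float] = COMPONENT_DENSITIES,
    moisture_dry_basis: Optional[float] = None,
) -> Dict[str, float]:
    """Component volume fractions from masses and densities.

    If ``moisture_dry_basis`` is given, a 'water' component with mass
    moisture * (sum of dry masses) is added.  Fractions sum to 1.
    """
    masses = dict(mass_comp)
    if any(v < 0 for v in masses.values()):
        raise ValueError("masses must be non-negative")
    if moisture_dry_basis is not None:
        masses["water"] = masses.get("water", 0.0) + moisture_dry_basis * sum(
            v for k, v in masses.items() if k != "water"
        )
    volumes = {}
    for name, mass in masses.items():
        if name not in densities:
            raise KeyError(f"no density provided for component '{name}'")
        volumes[name] = mass / densities[name]
    total = sum(volumes.values())
    if total <= 0:
        raise ValueError("total volume is zero")
    return {k: v / total for k, v in volumes.items()}


def conformer_allocation(xylose_count: float, twofold_share: float) -> Tuple[int, int]:
    """Integer (2-fold, 3-fold) xylose split for presentation.

    The 2-fold count is the rounded ``count * share``; the 3-fold count
    takes the remainder of the rounded total.
    """
    if xylose_count < 0:
        raise ValueError("xylose count must be non-negative")
    if not 0 <= twofold_share <= 1:
        raise ValueError("2-fold share must be in [0, 1]")
    total = _round_half_up(xylose_count)
    n2 = _round_half_up(xylose_count * twofold_share)
    n2 = min(n2, total)
    return n2, total - n2


#: default schematic bead radii, Å
BEAD_RADII: Dict[str, float] = {
    "xylose_2fold": 3.0,
    "xylose_3fold": 3.0,
    "arabinose": 3.0,
    "lignin": 3.0,
    "water": 1.9,
}

#: water beads drawn per fibril in the cross-section schematic: the
#: stoichiometric 110 scaled down for water's lower linear density along
#: the fibril axis.
SCHEMATIC_WATER_COUNT = 60


@dataclass
class SchematicLayout:
    """Bead placements of matrix components around the disk packing."""

    species: np.ndarray  # str array, one per bead
    positions: np.ndarray  # (n, 2) Å
    radii: np.ndarray  # Å per bead
    box_side: float
    metadata: dict = field(default_factory=dict)

    def save(self, csv_path) -> None:
        lines = ["species,x,y,radius"]
        for s, (x, y), r in zip(self.species, self.positions, self.radii):
            lines.append(f"{s},{x:.6g},{y:.6g},{r:.4g}")
        Path(csv_path).write_text("\n".join(lines) + "\n")


def schematic_layout(
    config: DiskConfiguration,
    counts_per_fibril: Mapping[str, float],
    bead_radii: Mapping[str, float] = BEAD_RADII,
    seed: int = 0,
    max_attempts_per_bead: int = 10000,
) -> SchematicLayout:
    """Scatter matrix beads uniformly in the inter-fibril space.

    ``counts_per_fibril`` gives beads per disk (rounded half-up times the
    number of disks is placed exactly).  Beads are rejection-sampled so
    that no bead overlaps a physical disk; bead-bead overlap is allowed
    (the schematic conveys density, not a packing).
    """
    rng = np.random.default_rng(seed)
    n_disks = config.n_disks
    L = config.box_side
    R = config.radius_phys
    species, radii, counts = [], [], []
    for name, per_fib in counts_per_fibril.items():
        if name not in bead_radii:
            raise KeyError(f"no bead radius for species '{name}'")
        total = _round_half_up(per_fib * n_disks)
        species.append(name)
        radii.append(bead_radii[name])
        counts.append(total)

    matrix_area = L * L * (1.0 - config.phi_phys)
    bead_area = sum(c * np.pi * r * r for c, r in zip(counts, radii))
    if bead_area > matrix_area:
        raise ValueError(
            f"requested bead area {bead_area:.3g} Å² exceeds matrix area "
            f"{matrix_area:.3g} Å²"
        )

    centers = config.centers
    out_species, out_pos, out_rad = [], [], []
    for name, r_bead, total in zip(species, radii, counts):
        limit2 = (R + r_bead) ** 2
        placed = 0
        attempts = 0
        while placed < total:
            attempts += 1
            if attempts > max_attempts_per_bead * max(total, 1):
                raise RuntimeError(
                    f"could not place '{name}' beads: matrix too crowded"
                )
            x, y = rng.random(2) * L
            dx = centers[:, 0] - x
            dy = centers[:, 1] - y
            dx -= L * np.rint(dx / L)
            dy -= L * np.rint(dy / L)
            if np.min(dx * dx + dy * dy) < limit2:
                continue
            out_species.append(name)
            out_pos.append((x, y))
            out_rad.append(r_bead)
            placed += 1
    return SchematicLayout(
        species=np.asarray(out_species, dtype=object),
        positions=np.asarray(out_pos, dtype=float).reshape(-1, 2),
        radii=np.asarray(out_rad, dtype=float),
        box_side=L,
        metadata={
            "seed": seed,
            "n_disks": n_disks,
            "counts": dict(zip(species, counts)),
        },
    )
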