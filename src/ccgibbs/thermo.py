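"""Legendre transforms between transformed and chemical Gibbs energies.

Equilibrium constants are measured at some pH and ionic strength, where every
compound is a pseudoisomer group: a Boltzmann-weighted mixture of its
protonation microspecies.  Linear regression on formation energies, however,
needs *chemical* standard Gibbs energies of single reference species.  This
module implements the (inverse) Legendre transform connecting the two, with
extended Debye–Hückel ionic-strength corrections, plus the elementary
K' <-> ΔG'° conversion.

Conventions
-----------
* Energies in kJ/mol, temperature in K, ionic strength in M.
* Each compound has exactly one reference microspecies with formation-energy
  offset 0; all other microspecies carry finite offsets relative to it.
* Metal-ion (e.g. Mg2+) binding and the temperature dependence of the
  transform are deliberately out of scope: K' is converted at its measurement
  temperature and no further correction to 298.15 K is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "R_KJ_PER_MOL_K",
    "ThermoConstants",
    "Conditions",
    "SpeciesRecord",
    "debye_huckel_term",
    "species_transform",
    "pseudoisomer_group_energy",
    "compound_transform",
    "transform_reaction",
    "reverse_transform_reaction",
    "keq_to_dg",
    "dg_to_keq",
]

#: Molar gas constant, kJ mol^-1 K^-1 (CODATA).
R_KJ_PER_MOL_K = 8.31446261815324e-3


def _alberty_alpha(T: float) -> float:
    """Debye–Hückel α(T) in kJ mol^-1 M^-1/2 (Alberty's cubic in T).

    Evaluates to ≈2.915 kJ/mol/M^1/2 at 298.15 K.
    """
    return 9.20483e-3 * T - 1.284668e-5 * T**2 + 4.95199e-8 * T**3


@dataclass(frozen=True)
class ThermoConstants:
    """Physical constants of the transform; swap parameterizations here."""

    R: float = R_KJ_PER_MOL_K
    debye_huckel_beta: float = 1.6  # M^-1/2

    def debye_huckel_alpha(self, T: float) -> float:
        return _alberty_alpha(T)


@dataclass(frozen=True)
class Conditions:
    """Aqueous measurement conditions: temperature, pH and ionic strength."""

    T: float = 298.15
    pH: float = 7.0
    ionic_strength: float = 0.25

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")
        if self.ionic_strength < 0:
            raise ValueError(
                f"ionic strength must be nonnegative, got {self.ionic_strength}"
            )


@dataclass(frozen=True)
class SpeciesRecord:
    """One protonation microspecies of a compound.

    ``dgf_offset`` is the chemical formation energy relative to the
    compound's reference species (0 for the reference itself); ``n_h`` is the
    hydrogen-atom count and ``z`` the net charge.
    """

    compound_id: str
    dgf_offset: float
    n_h: int
    z: int
    is_reference: bool = False


def debye_huckel_term(cond: Conditions, const: ThermoConstants | None = None) -> float:
    """Extended Debye–Hückel activity term α(T)·√I / (1 + β·√I), kJ/mol.

    Zero at zero ionic strength, strictly increasing in I.
    """
    const = const or ThermoConstants()
    if cond.ionic_strength < 0:
        raise ValueError("ionic strength must be nonnegative")
    sqrt_i = math.sqrt(cond.ionic_strength)
    alpha = const.debye_huckel_alpha(cond.T)
    return alpha * sqrt_i / (1.0 + const.debye_huckel_beta * sqrt_i)


def species_transform(
    sp: SpeciesRecord, cond: Conditions, const: ThermoConstants | None = None
) -> float:
    """Legendre-transform shift of one microspecies, kJ/mol.

    Returns ΔGf'° relative to the compound's reference chemical species:

        offset + n_H·R·T·ln(10)·pH − (z² − n_H)·DH(I, T)
    """
    const = const or ThermoConstants()
    dh = debye_huckel_term(cond, const)
    return (
        sp.dgf_offset
        + sp.n_h * const.R * cond.T * math.log(10.0) * cond.pH
        - (sp.z**2 - sp.n_h) * dh
    )


def pseudoisomer_group_energy(energies, T: float, const: ThermoConstants | None = None) -> float:
    """Boltzmann-weighted (soft-min) energy of coexisting microspecies.

    Computes −R·T·ln Σ_j exp(−g_j / (R·T)) via a shifted log-sum-exp, so
    offsets of hundreds of kJ/mol do not overflow.  The result is always at
    or below the minimum input energy.
    """
    const = const or ThermoConstants()
    g = np.asarray(list(energies), dtype=float)
    if g.size == 0:
        raise ValueError("pseudoisomer group must contain at least one species")
    rt = const.R * T
    return float(-rt * logsumexp(-g / rt))


def compound_transform(
    species: list[SpeciesRecord],
    cond: Conditions,
    const: ThermoConstants | None = None,
) -> float:
    """Per-compound correction ΔGf'°(pseudoisomer group) − ΔGf°(reference).

    The reference species has offset 0, so this is just the pseudoisomer
    group energy of the transformed offsets.
    """
    const = const or ThermoConstants()
    transformed = [species_transform(sp, cond, const) for sp in species]
    return pseudoisomer_group_energy(transformed, cond.T, const)


def transform_reaction(
    reaction: dict[str, float],
    dg_standard: float,
    cond: Conditions,
    species_db: dict[str, list[SpeciesRecord]],
    const: ThermoConstants | None = None,
) -> float:
    """Forward Legendre transform: chemical ΔG° → transformed ΔG'° at ``cond``."""
    const = const or ThermoConstants()
    shift = 0.0
    for cid, coeff in reaction.items():
        if cid not in species_db:
            raise KeyError(f"no species data for compound {cid!r}")
        shift += coeff * compound_transform(species_db[cid], cond, const)
    return dg_standard + shift


def reverse_transform_reaction(
    reaction: dict[str, float],
    dg_prime: float,
    cond: Conditions,
    species_db: dict[str, list[SpeciesRecord]],
    const: ThermoConstants | None = None,
) -> float:
    """Inverse Legendre transform: measured ΔG'° → chemical ΔG° over reference species.

    Subtracts, for each compound, the pseudoisomer-group energy of its
    transformed microspecies (relative to the reference species, whose offset
    is zero) weighted by the stoichiometric coefficient.

    Raises
    ------
    KeyError
        If a compound of the reaction is missing from ``species_db``.
    """
    const = const or ThermoConstants()
    shift = 0.0
    missing = [cid for cid in reaction if cid not in species_db]
    if missing:
        raise KeyError(
            "no species data for compound(s): " + ", ".join(sorted(missing))
        )
    for cid, coeff in reaction.items():
        shift += coeff * compound_transform(species_db[cid], cond, const)
    return dg_prime - shift


def keq_to_dg(k_prime: float, T: float, const: ThermoConstants | None = None) -> float:
    """Convert an apparent equilibrium constant K' to ΔG'° = −R·T·ln K' (kJ/mol)."""
    const = const or ThermoConstants()
    if k_prime <= 0:
        raise ValueError(f"equilibrium constant must be positive, got {k_prime}")
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return -const.R * T * math.log(k_prime)


def dg_to_keq(dg_prime: float, T: float, const: ThermoConstants | None = None) -> float:
    """Inverse of :func:`keq_to_dg`."""
    const = const or ThermoConstants()
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return math.exp(-dg_prime / (const.R * T))


# --- species table I/O ------------------------------------------------------

def read_species_table(path, const: ThermoConstants | None = None) -> dict[str, list[SpeciesRecord]]:
    """Read a compound microspecies table (TSV).

    Columns: compound_id, species_index, is_reference (0/1), n_H, z and either
    ``dGf_offset_kj_mol`` (explicit energy offsets) or ``pKa_step`` (a ladder:
    each non-reference row's offset is derived from the cumulative pKa steps
    away from the reference, R·T·ln(10)·pKa per proton at 298.15 K).
    """
    import pandas as pd

    const = const or ThermoConstants()
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"compound_id", "species_index", "is_reference", "n_H", "z"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"species table missing columns: {sorted(missing_cols)}")
    has_offset = "dGf_offset_kj_mol" in df.columns
    has_pka = "pKa_step" in df.columns
    if not (has_offset or has_pka):
        raise ValueError(
            "species table needs a dGf_offset_kj_mol or pKa_step column"
        )
    db: dict[str, list[SpeciesRecord]] = {}
    rt_ln10 = const.R * 298.15 * math.log(10.0)
    for cid, grp in df.groupby("compound_id", sort=True):
        grp = grp.sort_values("species_index")
        refs = grp["is_reference"].astype(int).sum()
        if refs != 1:
            raise ValueError(
                f"compound {cid!r} must have exactly one reference species, found {refs}"
            )
        records: list[SpeciesRecord] = []
        if has_offset and grp["dGf_offset_kj_mol"].notna().all():
            for row in grp.itertuples():
                records.append(
                    SpeciesRecord(
                        compound_id=str(cid),
                        dgf_offset=float(row.dGf_offset_kj_mol),
                        n_h=int(row.n_H),
                        z=int(row.z),
                        is_reference=bool(int(row.is_reference)),
                    )
                )
        elif has_pka:
            # pKa ladder: rows ordered by species_index, reference anywhere in
            # the ladder; offset difference between adjacent rows is
            # RT·ln(10)·pKa_step of the more protonated one.
            rows = list(grp.itertuples())
            ref_pos = next(
                i for i, r in enumerate(rows) if int(r.is_reference) == 1
            )
            offsets = [0.0] * len(rows)
            for i in range(ref_pos + 1, len(rows)):
                step = float(rows[i].pKa_step)
                offsets[i] = offsets[i - 1] - rt_ln10 * step
            for i in range(ref_pos - 1, -1, -1):
                step = float(rows[i + 1].pKa_step)
                offsets[i] = offsets[i + 1] + rt_ln10 * step
            for off, row in zip(offsets, rows):
                records.append(
                    SpeciesRecord(
                        compound_id=str(cid),
                        dgf_offset=off,
                        n_h=int(row.n_H),
                        z=int(row.z),
                        is_reference=bool(int(row.is_reference)),
                    )
                )
        else:
            raise ValueError(f"compound {cid!r}: missing offsets and no pKa ladder")
        ref = [r for r in records if r.is_reference]
        if abs(ref[0].dgf_offset) > 1e-9:
            raise ValueError(
                f"compound {cid!r}: reference species must have offset 0"
            )
        db[str(cid)] = records
    return db


def write_species_table(path, species_db: dict[str, list[SpeciesRecord]]) -> None:
    """Write a species table in the explicit-offset dialect."""
    import pandas as pd

    rows = []
    for cid in sorted(species_db):
        for idx, sp in enumerate(species_db[cid]):
            rows.append(
                {
                    "compound_id": cid,
                    "species_index": idx,
                    "is_reference": int(sp.is_reference),
                    "n_H": sp.n_h,
                    "z": sp.z,
                    "dGf_offset_kj_mol": sp.dgf_offset,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
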