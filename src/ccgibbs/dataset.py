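"""Ingest reaction measurements and assemble the regression inputs.

The training pipeline is: read raw observation rows (apparent equilibrium
constants K', transformed Gibbs energies ΔG'°, or already-chemical ΔG°) →
standardize every row to a chemical ΔG° via the inverse Legendre transform →
canonicalize reaction vectors so replicates of the same chemical reaction
share one key → aggregate replicates by their median → optionally project the
observation vector onto the subspace of first-law-consistent vectors
(the row space of S).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd

from . import thermo
from .linalg import projectors

__all__ = [
    "ReactionVector",
    "ObservationRecord",
    "TrainingData",
    "parse_reaction",
    "format_reaction",
    "read_observations",
    "write_observations",
    "standardize",
    "canonicalize_reaction",
    "aggregate_replicates",
    "project_observations",
    "build_training_data",
]

VALUE_KINDS = ("K_prime", "dG_prime", "dG_standard")


@dataclass(frozen=True)
class ReactionVector:
    """Sparse stoichiometric vector: compound id → signed coefficient.

    Products carry positive coefficients, substrates negative.  Zero-valued
    entries are never stored.  An empty vector is permitted only as a query
    (a null net reaction); training rejects it.
    """

    coefficients: tuple[tuple[str, float], ...]

    @staticmethod
    def from_dict(d: dict[str, float]) -> "ReactionVector":
        items = tuple(sorted((k, float(v)) for k, v in d.items() if v != 0))
        return ReactionVector(coefficients=items)

    def as_dict(self) -> dict[str, float]:
        return dict(self.coefficients)

    def compounds(self) -> list[str]:
        return [c for c, _ in self.coefficients]

    def __neg__(self) -> "ReactionVector":
        return ReactionVector(tuple((c, -v) for c, v in self.coefficients))

    def is_empty(self) -> bool:
        return len(self.coefficients) == 0

    def to_dense(self, compound_index: list[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(compound_index)}
        x = np.zeros(len(compound_index))
        for c, v in self.coefficients:
            if c not in pos:
                raise KeyError(f"compound {c!r} not in index")
            x[pos[c]] = v
        return x


@dataclass(frozen=True)
class ObservationRecord:
    """One raw measurement row."""

    reaction: ReactionVector
    value_kind: str
    value: float
    conditions: thermo.Conditions
    weight: float = 1.0
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"unknown value_kind {self.value_kind!r}; expected one of {VALUE_KINDS}"
            )
        if self.value_kind == "K_prime" and self.value <= 0:
            raise ValueError(f"K' must be positive, got {self.value}")
        if not math.isfinite(self.weight) or self.weight < 0:
            raise ValueError(f"weight must be finite and nonnegative, got {self.weight}")


@dataclass
class TrainingData:
    """Assembled regression input.

    ``S`` is the m×n stoichiometric matrix (compounds × unique reactions);
    column j is the canonical vector of reaction j.  ``dG_obs`` holds the
    median-aggregated chemical standard Gibbs energies (kJ/mol).
    ``projected_ss`` carries the sum of squares removed by
    :func:`project_observations` so error variances can still be estimated
    from projected data.
    """

    S: np.ndarray
    dG_obs: np.ndarray
    weights: np.ndarray
    compound_index: list[str]
    reaction_index: list[tuple]
    replicate_counts: np.ndarray
    replicate_values: list[list[float]] = field(default_factory=list)
    projected_ss: float = 0.0

    @property
    def n_compounds(self) -> int:
        return self.S.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    def reaction_vector(self, j: int) -> ReactionVector:
        col = self.S[:, j]
        return ReactionVector.from_dict(
            {c: col[i] for i, c in enumerate(self.compound_index) if col[i] != 0}
        )


# --- reaction formula grammar ----------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?|\d+/\d+)\s+)?(\S+)$")


def parse_reaction(formula: str) -> ReactionVector:
    """Parse ``"2 C00001 + C00002 = C00008 + C00009"`` into a ReactionVector.

    Sides are joined by ``=`` or ``<=>``; terms by ``+``; a term is
    ``[coefficient] compound_id`` with coefficient defaulting to 1.
    Compounds appearing on both sides have their coefficients netted.
    """
    parts = re.split(r"<=>|=", formula)
    if len(parts) != 2:
        raise ValueError(f"reaction must have exactly two sides: {formula!r}")
    coeffs: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            m = _TERM_RE.match(term)
            if m is None:
                raise ValueError(f"cannot parse reaction term {term!r} in {formula!r}")
            coef_str, cid = m.groups()
            if coef_str is None:
                coef = 1.0
            elif "/" in coef_str:
                coef = float(Fraction(coef_str))
            else:
                coef = float(coef_str)
            coeffs[cid] = coeffs.get(cid, 0.0) + sign * coef

    add_side(parts[0], -1.0)
    add_side(parts[1], +1.0)
    return ReactionVector.from_dict(coeffs)


def format_reaction(r: ReactionVector) -> str:
    """Inverse of :func:`parse_reaction` (canonical spacing, integer-friendly)."""

    def fmt(cid: str, v: float) -> str:
        a = abs(v)
        coef = "" if a == 1 else (f"{int(a)} " if a == int(a) else f"{a:g} ")
        return f"{coef}{cid}"

    subs = [fmt(c, v) for c, v in r.coefficients if v < 0]
    prods = [fmt(c, v) for c, v in r.coefficients if v > 0]
    return " + ".join(subs) + " = " + " + ".join(prods)


# --- observation TSV I/O ----------------------------------------------------

OBS_COLUMNS = ["reaction", "value_kind", "value", "T_K", "pH", "I_M", "weight", "source_id"]


def read_observations(path, default_conditions: thermo.Conditions | None = None) -> list[ObservationRecord]:
    """Read an observation TSV; malformed rows raise with their line number."""
    defaults = default_conditions or thermo.Conditions()
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"source_id": str})
    if df.empty and "reaction" not in df.columns:
        return []
    records: list[ObservationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rxn = parse_reaction(str(row.reaction))
            cond = thermo.Conditions(
                T=_opt(row, "T_K", defaults.T),
                pH=_opt(row, "pH", defaults.pH),
                ionic_strength=_opt(row, "I_M", defaults.ionic_strength),
            )
            records.append(
                ObservationRecord(
                    reaction=rxn,
                    value_kind=str(row.value_kind),
                    value=float(row.value),
                    conditions=cond,
                    weight=_opt(row, "weight", 1.0),
                    source_id=str(getattr(row, "source_id", "") or ""),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return records


def _opt(row, name: str, default: float) -> float:
    v = getattr(row, name, None)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return default
    return float(v)


def write_observations(path, records: list[ObservationRecord], header: str | None = None) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "reaction": format_reaction(rec.reaction),
                "value_kind": rec.value_kind,
                "value": rec.value,
                "T_K": rec.conditions.T,
                "pH": rec.conditions.pH,
                "I_M": rec.conditions.ionic_strength,
                "weight": rec.weight,
                "source_id": rec.source_id,
            }
        )
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=OBS_COLUMNS).to_csv(fh, sep="\t", index=False)


# --- standardization --------------------------------------------------------

def standardize(
    observations: list[ObservationRecord],
    species_db: dict[str, list[thermo.SpeciesRecord]] | None,
    const: thermo.ThermoConstants | None = None,
) -> list[tuple[ReactionVector, float, float, str]]:
    """Convert every observation to a chemical standard Gibbs energy.

    K' rows go through −RT ln K' followed by the inverse Legendre transform;
    ΔG'° rows go through the inverse transform only; ΔG° rows pass through
    unchanged.  Returns (reaction, dG_standard, weight, source_id) tuples in
    input order.

    Raises
    ------
    KeyError
        If a K'/ΔG'° observation involves a compound missing from
        ``species_db`` (the error lists the compounds).
    """
    const = const or thermo.ThermoConstants()
    out = []
    for rec in observations:
        if rec.value_kind == "dG_standard":
            dg0 = rec.value
        else:
            if rec.value_kind == "K_prime":
                dg_prime = thermo.keq_to_dg(rec.value, rec.conditions.T, const)
            else:
                dg_prime = rec.value
            if species_db is None:
                raise KeyError(
                    "species table required to standardize K'/dG' observations for "
                    + format_reaction(rec.reaction)
                )
            dg0 = thermo.reverse_transform_reaction(
                rec.reaction.as_dict(), dg_prime, rec.conditions, species_db, const
            )
        out.append((rec.reaction, dg0, rec.weight, rec.source_id))
    return out


# --- canonicalization -------------------------------------------------------

def canonicalize_reaction(r: ReactionVector) -> tuple[tuple, float]:
    """Canonical key and rescaling factor of a reaction.

    Coefficients are rescaled to coprime integers (when they are rationals
    with modest denominators) and the orientation is fixed so that the
    lexicographically smallest compound id with a nonzero coefficient has a
    negative sign.  Returns ``(key, factor)`` with
    ``canonical_vector = factor * original_vector``; the caller multiplies
    the observed ΔG by the same signed factor (for unit-scaled reactions the
    factor is just the orientation sign ±1).
    """
    if r.is_empty():
        raise ValueError("cannot canonicalize an empty reaction")
    fracs = [Fraction(v).limit_denominator(10**6) for _, v in r.coefficients]
    lcm = 1
    for f in fracs:
        lcm = lcm * f.denominator // math.gcd(lcm, f.denominator)
    ints = [int(f * lcm) for f in fracs]
    g = 0
    for v in ints:
        g = math.gcd(g, abs(v))
    if g > 0:
        ints = [v // g for v in ints]
    first = min(c for c, _ in r.coefficients)
    first_val = ints[[c for c, _ in r.coefficients].index(first)]
    sign = -1 if first_val > 0 else 1
    key = tuple((c, sign * v) for (c, _), v in zip(r.coefficients, ints))
    # factor maps the original coefficients onto the canonical integers
    factor = sign * float(Fraction(lcm, g if g else 1))
    return key, factor


def key_to_reaction(key: tuple) -> ReactionVector:
    return ReactionVector.from_dict({c: float(v) for c, v in key})


# --- aggregation ------------------------------------------------------------

def aggregate_replicates(
    standardized: list[tuple[ReactionVector, float, float, str]],
    weight_policy: str = "sum",
    compound_index: list[str] | None = None,
) -> TrainingData:
    """Merge replicate measurements of the same chemical reaction.

    Observations sharing a canonical key are collapsed into one column of S;
    the training value is the median of the orientation-corrected ΔG° values
    (median, not mean, for robustness to outliers).  ``weight_policy`` is
    ``"sum"``, ``"mean"`` or ``"none"`` and controls how per-row weights
    combine; the default training path is unweighted after aggregation, with
    replicate counts retained for diagnostics.

    ``compound_index`` may supply a compound universe that is a superset of
    the compounds appearing in the observations (e.g. compounds known only
    through the group table); their rows of S are zero.
    """
    if not standardized:
        raise ValueError("no observations to aggregate")
    if weight_policy not in ("sum", "mean", "none"):
        raise ValueError(f"unknown weight policy {weight_policy!r}")
    groups: dict[tuple, dict] = {}
    order: list[tuple] = []
    for rxn, dg0, w, src in standardized:
        if rxn.is_empty():
            raise ValueError("empty reaction in training observations")
        key, factor = canonicalize_reaction(rxn)
        if key not in groups:
            groups[key] = {"values": [], "weights": []}
            order.append(key)
        groups[key]["values"].append(factor * dg0)
        groups[key]["weights"].append(w)
    order = sorted(order)
    observed = {c for key in order for c, _ in key}
    if compound_index is None:
        compound_ids = sorted(observed)
    else:
        missing = observed - set(compound_index)
        if missing:
            raise ValueError(
                f"compound_index missing observed compounds: {sorted(missing)}"
            )
        compound_ids = list(compound_index)
    m, n = len(compound_ids), len(order)
    pos = {c: i for i, c in enumerate(compound_ids)}
    S = np.zeros((m, n))
    dg = np.zeros(n)
    weights = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    rep_values: list[list[float]] = []
    for j, key in enumerate(order):
        for c, v in key:
            S[pos[c], j] = v
        vals = groups[key]["values"]
        dg[j] = float(np.median(vals))
        counts[j] = len(vals)
        rep_values.append(list(vals))
        ws = groups[key]["weights"]
        if weight_policy == "sum":
            weights[j] = float(np.sum(ws))
        elif weight_policy == "mean":
            weights[j] = float(np.mean(ws))
        else:
            weights[j] = 1.0
    return TrainingData(
        S=S,
        dG_obs=dg,
        weights=weights,
        compound_index=compound_ids,
        reaction_index=order,
        replicate_counts=counts,
        replicate_values=rep_values,
    )


def build_training_data(
    observations: list[ObservationRecord],
    species_db: dict[str, list[thermo.SpeciesRecord]] | None = None,
    const: thermo.ThermoConstants | None = None,
    weight_policy: str = "sum",
    compound_index: list[str] | None = None,
) -> TrainingData:
    """standardize → aggregate in one call."""
    return aggregate_replicates(
        standardize(observations, species_db, const),
        weight_policy=weight_policy,
        compound_index=compound_index,
    )


# --- projection onto the consistent subspace --------------------------------

def project_observations(td: TrainingData, rel_tol: float | None = None) -> TrainingData:
    """Project dG_obs onto the row space of S (range of Sᵀ).

    Observation vectors of real reactions must satisfy the first law: they
    must be expressible as Sᵀ·f for some formation-energy vector f.  Any
    orthogonal component is experimental error and is removed here.  The sum
    of squares removed is accumulated in ``projected_ss`` so that downstream
    error-variance estimation still sees the full residual (projection is a
    no-op for the least-squares point estimates themselves).
    """
    pp = projectors(td.S.T, rel_tol)
    projected = pp.P_range @ td.dG_obs
    removed = float(np.sum((td.dG_obs - projected) ** 2))
    return replace(
        td, dG_obs=projected, projected_ss=td.projected_ss + removed
    )
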