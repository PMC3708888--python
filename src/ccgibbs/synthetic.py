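"""Self-contained synthetic training worlds.

Generates data with exactly the statistical structure the estimator assumes:
group contributions drawn at a realistic energy scale, per-compound
deviations from group additivity (the "non-additivity" error, anchored at
the ~6.8 kJ/mol scale typical of curated group models), sparse integer
reaction stoichiometries, replicate measurements with additive Gaussian
noise, and optional orphan compounds whose unique group never appears in
any measured reaction (these exercise the uncovered/novel-group path).

Everything is deterministic given the seed, and the writers emit the same
TSV dialects the dataset/groups readers consume, so the full pipeline runs
with no external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from . import thermo
from .dataset import (
    ObservationRecord,
    ReactionVector,
    TrainingData,
    aggregate_replicates,
    canonicalize_reaction,
    write_observations,
)
from .groups import GroupIncidence, write_group_incidence

__all__ = ["SimConfig", "SyntheticWorld", "generate", "make_query_suite", "write_world"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic world.

    Defaults mirror the empirical regime the method targets: non-additivity
    error around 6.8 kJ/mol dominating a ~1 kJ/mol measurement noise, about
    six replicate measurements per unique reaction, group energies on the
    tens-of-kJ/mol scale.
    """

    m_compounds: int = 25
    g_groups: int = 8
    n_reactions: int = 40
    replicate_mean: float = 6.0
    sigma_noise: float = 1.0  # kJ/mol, per-measurement
    sigma_nonadditivity: float = 6.8  # kJ/mol, per-compound deviation from additivity
    group_energy_scale: float = 30.0  # kJ/mol
    sparsity: float = 0.3  # probability a compound carries a given group
    seed: int = 0
    n_orphan_compounds: int = 0  # compounds with a unique group, never measured
    measured_fraction: float = 0.8  # fraction of compounds reachable by measurements
    value_kind: str = "dG_standard"  # or "K_prime"
    protonatable_fraction: float = 0.4

    def __post_init__(self) -> None:
        if min(self.m_compounds, self.g_groups, self.n_reactions) <= 0:
            raise ValueError("dimensions must be positive")
        if min(self.sigma_noise, self.sigma_nonadditivity, self.group_energy_scale) < 0:
            raise ValueError("scales must be nonnegative")
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError("sparsity must be in (0, 1]")
        if self.value_kind not in ("dG_standard", "K_prime"):
            raise ValueError(f"unsupported value_kind {self.value_kind!r}")
        if self.replicate_mean < 1.0:
            raise ValueError("replicate_mean must be >= 1")
        if not 0.0 < self.measured_fraction <= 1.0:
            raise ValueError("measured_fraction must be in (0, 1]")
        if max(2, round(self.measured_fraction * self.m_compounds)) < 2:
            raise ValueError("too few measurable compounds")


@dataclass
class SyntheticWorld:
    """A generated world: inputs plus the ground truth behind them."""

    config: SimConfig
    compound_index: list[str]
    group_index: list[str]
    incidence: GroupIncidence
    observations: list[ObservationRecord]
    species_db: dict[str, list[thermo.SpeciesRecord]]
    reactions: list[ReactionVector]  # unique training reactions
    dGf_true: np.ndarray
    dg_true: np.ndarray
    delta: np.ndarray  # per-compound non-additivity deviations

    def training_data(self) -> TrainingData:
        """Aggregate the raw observations over the full compound universe."""
        from .dataset import standardize

        std = standardize(self.observations, self.species_db)
        return aggregate_replicates(std, compound_index=self.compound_index)

    def true_dg(self, x: ReactionVector) -> float:
        return float(x.to_dense(self.compound_index) @ self.dGf_true)


def generate(cfg: SimConfig) -> SyntheticWorld:
    """Sample a complete world from the generative model.

    dg_true ~ N(0, group_energy_scale²); per-compound deviation
    δ ~ N(0, sigma_nonadditivity²); dGf_true = G·dg_true + δ; unique sparse
    integer reactions with coefficients in {−3..3} and ≥2 distinct
    compounds; replicate counts 1 + Poisson(replicate_mean − 1);
    observations Sᵀ·dGf_true + N(0, sigma_noise²).
    """
    rng = np.random.default_rng(cfg.seed)
    m, g, n = cfg.m_compounds, cfg.g_groups, cfg.n_reactions
    m_total = m + cfg.n_orphan_compounds
    g_total = g + cfg.n_orphan_compounds
    compounds = [f"C{i:04d}" for i in range(1, m_total + 1)]
    groups_ids = [f"g{j:03d}" for j in range(1, g_total + 1)]

    # incidence: measured compounds draw from the first g groups; each orphan
    # compound carries one private group that no reaction will ever touch.
    G = np.zeros((m_total, g_total))
    for i in range(m):
        mask = rng.random(g) < cfg.sparsity
        if not mask.any():
            mask[rng.integers(g)] = True
        G[i, :g][mask] = rng.integers(1, 4, size=int(mask.sum()))
    for k in range(cfg.n_orphan_compounds):
        i = m + k
        mask = rng.random(g) < cfg.sparsity
        G[i, :g][mask] = rng.integers(1, 4, size=int(mask.sum()))
        G[i, g + k] = 1.0
    incidence = GroupIncidence(G, compounds, groups_ids, set())

    dg_true = rng.normal(0.0, cfg.group_energy_scale, size=g_total)
    delta = rng.normal(0.0, cfg.sigma_nonadditivity, size=m_total)
    dGf_true = G @ dg_true + delta

    # unique sparse integer reactions over the measured subset of compounds;
    # the rest of the universe is reachable only through the group layer,
    # mimicking corpora where measurements concentrate in central metabolism
    m_meas = max(2, round(cfg.measured_fraction * m))
    reactions: list[ReactionVector] = []
    seen_keys: set = set()
    attempts = 0
    max_attempts = 200 * n
    while len(reactions) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "could not sample the requested number of unique reactions; "
                "increase m_compounds or decrease n_reactions"
            )
        k = int(rng.integers(2, min(5, m_meas) + 1))
        idx = rng.choice(m_meas, size=k, replace=False)
        coeffs = rng.integers(1, 4, size=k) * rng.choice([-1, 1], size=k)
        if np.all(coeffs > 0) or np.all(coeffs < 0):
            coeffs[0] = -coeffs[0]
        rxn = ReactionVector.from_dict(
            {compounds[i]: float(c) for i, c in zip(idx, coeffs)}
        )
        key, _ = canonicalize_reaction(rxn)
        if key in seen_keys:
            continue
        seen_keys.add(key)
        # store the canonical (coprime, oriented) form so every observation
        # carries noise at the same stoichiometric scale
        reactions.append(ReactionVector.from_dict({c: float(v) for c, v in key}))

    species_db = _sample_species(rng, compounds, cfg)
    const = thermo.ThermoConstants()

    observations: list[ObservationRecord] = []
    for j, rxn in enumerate(reactions):
        x = rxn.to_dense(compounds)
        true_val = float(x @ dGf_true)
        n_rep = 1 + int(rng.poisson(cfg.replicate_mean - 1.0))
        for r in range(n_rep):
            dg0 = true_val + rng.normal(0.0, cfg.sigma_noise)
            if cfg.value_kind == "dG_standard":
                cond = thermo.Conditions()
                rec = ObservationRecord(
                    reaction=rxn,
                    value_kind="dG_standard",
                    value=dg0,
                    conditions=cond,
                    source_id=f"R{j:04d}.{r}",
                )
            else:
                cond = thermo.Conditions(
                    T=298.15,
                    pH=float(rng.uniform(5.0, 9.0)),
                    ionic_strength=float(rng.uniform(0.0, 0.35)),
                )
                dg_prime = thermo.transform_reaction(
                    rxn.as_dict(), dg0, cond, species_db, const
                )
                # reactions far from equilibrium have no representable K';
                # report those rows as dG_prime, as measurement corpora do
                if abs(dg_prime) < 700.0 * const.R * cond.T:
                    kind, value = "K_prime", thermo.dg_to_keq(dg_prime, cond.T, const)
                else:
                    kind, value = "dG_prime", dg_prime
                rec = ObservationRecord(
                    reaction=rxn,
                    value_kind=kind,
                    value=value,
                    conditions=cond,
                    source_id=f"R{j:04d}.{r}",
                )
            observations.append(rec)

    return SyntheticWorld(
        config=cfg,
        compound_index=compounds,
        group_index=groups_ids,
        incidence=incidence,
        observations=observations,
        species_db=species_db,
        reactions=reactions,
        dGf_true=dGf_true,
        dg_true=dg_true,
        delta=delta,
    )


def _sample_species(rng, compounds: list[str], cfg: SimConfig):
    """Reference species for every compound; some get a protonated partner."""
    rt_ln10 = thermo.R_KJ_PER_MOL_K * 298.15 * math.log(10.0)
    db: dict[str, list[thermo.SpeciesRecord]] = {}
    for cid in compounds:
        n_h = int(rng.integers(0, 21))
        z = int(rng.integers(-2, 3))
        records = [
            thermo.SpeciesRecord(cid, 0.0, n_h, z, is_reference=True)
        ]
        if rng.random() < cfg.protonatable_fraction:
            pka = float(rng.uniform(4.0, 9.0))
            # more-protonated partner, offset −RT·ln(10)·pKa below the reference
            records.append(
                thermo.SpeciesRecord(cid, -rt_ln10 * pka, n_h + 1, z + 1)
            )
        db[cid] = records
    return db


def make_query_suite(
    world: SyntheticWorld,
    kinds: tuple[str, ...] = ("in_range", "mixed", "gc_only", "uncovered", "cycle"),
    n_per_kind: int = 5,
    rng: np.random.Generator | None = None,
) -> list[tuple[ReactionVector, float, str]]:
    """Construct query reactions of known class with their true energies.

    Classes: ``in_range`` (integer combinations of training reactions, RC
    fraction 1); ``mixed`` (an in-range combination plus unmeasured
    compounds, so 0 < RC fraction < 1); ``gc_only`` (unmeasured compounds
    only — wholly in null(Sᵀ), group-covered when the training reactions
    span group space); ``uncovered`` (touches an orphan compound's private
    group; requires ``n_orphan_compounds > 0``); ``cycle`` (the null net
    reaction, true ΔG° = 0).
    """
    rng = rng or np.random.default_rng(world.config.seed + 1)
    m = world.config.m_compounds
    m_meas = max(2, round(world.config.measured_fraction * m))
    unmeasured = list(range(m_meas, m))
    S = np.stack(
        [r.to_dense(world.compound_index) for r in world.reactions], axis=1
    )
    out: list[tuple[ReactionVector, float, str]] = []
    for kind in kinds:
        for _ in range(n_per_kind):
            if kind == "in_range":
                c = rng.integers(-2, 3, size=S.shape[1])
                if not np.any(c):
                    c[rng.integers(S.shape[1])] = 1
                x = S @ c
                rxn = _to_reaction(x, world.compound_index)
                if rxn.is_empty():
                    continue
            elif kind == "mixed":
                if not unmeasured:
                    raise ValueError(
                        "mixed queries need measured_fraction < 1 in the config"
                    )
                c = rng.integers(-1, 2, size=S.shape[1])
                if not np.any(c):
                    c[rng.integers(S.shape[1])] = 1
                x = S @ c
                i = unmeasured[int(rng.integers(len(unmeasured)))]
                x[i] += float(rng.choice([-1, 1]))
                rxn = _to_reaction(x, world.compound_index)
            elif kind == "gc_only":
                if not unmeasured:
                    raise ValueError(
                        "gc_only queries need measured_fraction < 1 in the config"
                    )
                k = min(len(unmeasured), int(rng.integers(1, 3)))
                idx = rng.choice(unmeasured, size=k, replace=False)
                coeffs = rng.integers(1, 3, size=k) * rng.choice([-1, 1], size=k)
                rxn = ReactionVector.from_dict(
                    {world.compound_index[i]: float(v) for i, v in zip(idx, coeffs)}
                )
            elif kind == "uncovered":
                if world.config.n_orphan_compounds == 0:
                    raise ValueError(
                        "uncovered queries need n_orphan_compounds > 0 in the config"
                    )
                orphan = m + int(rng.integers(world.config.n_orphan_compounds))
                partner = int(rng.integers(m))
                rxn = ReactionVector.from_dict(
                    {
                        world.compound_index[partner]: -1.0,
                        world.compound_index[orphan]: 1.0,
                    }
                )
            elif kind == "cycle":
                rxn = ReactionVector.from_dict({})
                out.append((rxn, 0.0, kind))
                continue
            else:
                raise ValueError(f"unknown query kind {kind!r}")
            out.append((rxn, world.true_dg(rxn), kind))
    return out


def sample_null_cycles(
    td: TrainingData, n_cycles: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random coefficient vectors c with S·c = 0 (zero net reactions).

    Returns an empty list when the training reactions are linearly
    independent (null space trivial).
    """
    from scipy.linalg import null_space

    ns = null_space(td.S)
    if ns.shape[1] == 0:
        return []
    out = []
    for _ in range(n_cycles):
        coeffs = rng.normal(size=ns.shape[1])
        out.append(ns @ coeffs)
    return out


def _to_reaction(x: np.ndarray, compound_index: list[str]) -> ReactionVector:
    return ReactionVector.from_dict(
        {c: float(v) for c, v in zip(compound_index, x) if v != 0}
    )


def write_world(world: SyntheticWorld, directory, header_extra: str = "") -> dict:
    """Write observations/species/groups TSVs plus a truth JSON.

    Returns the paths.  The truth file is for test harnesses only and never
    read by the training pipeline.
    """
    import hashlib
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(asdict(world.config), sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:12]
    header = f"ccgibbs synthetic world; seed={world.config.seed}; config_sha={cfg_hash}"
    if header_extra:
        header += f"; {header_extra}"

    paths = {
        "observations": directory / "observations.tsv",
        "species": directory / "species.tsv",
        "groups": directory / "groups.tsv",
        "truth": directory / "truth.json",
    }
    write_observations(paths["observations"], world.observations, header=header)
    write_group_incidence(paths["groups"], world.incidence, header=header)
    with open(paths["species"], "w") as fh:
        fh.write(f"# {header}\n")
        import pandas as pd

        rows = []
        for cid in sorted(world.species_db):
            for idx, sp in enumerate(world.species_db[cid]):
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
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    truth = {
        "seed": world.config.seed,
        "config": asdict(world.config),
        "compound_index": world.compound_index,
        "group_index": world.group_index,
        "dGf_true": world.dGf_true.tolist(),
        "dg_true": world.dg_true.tolist(),
        "delta": world.delta.tolist(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
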