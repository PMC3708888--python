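import math

import numpy as np
import pytest

from ccgibbs import thermo
from ccgibbs.dataset import (
    ObservationRecord,
    ReactionVector,
    TrainingData,
    aggregate_replicates,
    build_training_data,
    canonicalize_reaction,
    format_reaction,
    parse_reaction,
    project_observations,
    read_observations,
    standardize,
    write_observations,
)
from conftest import training_data_from_matrices

RT = thermo.R_KJ_PER_MOL_K * 298.15


class TestReactionParsing:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("2 C00001 + C00002 = C00008 + C00009",
             {"C00001": -2, "C00002": -1, "C00008": 1, "C00009": 1}),
            ("A <=> B", {"A": -1, "B": 1}),
            ("1/2 A = B", {"A": -0.5, "B": 1}),
            ("A + B = B + C", {"A": -1, "C": 1}),  # netting across sides
            ("A = A", {}),  # null net reaction
        ],
    )
    def test_grammar(self, formula, expected):
        assert parse_reaction(formula).as_dict() == expected

    def test_format_round_trip(self):
        r = parse_reaction("2 C00001 + C00002 = 3 C00008")
        assert parse_reaction(format_reaction(r)) == r

    @pytest.mark.parametrize("bad", ["A + B", "A = B = C"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_reaction(bad)


class TestObservationIO:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "obs.tsv"
        p.write_text("reaction\tvalue_kind\tvalue\tT_K\tpH\tI_M\tweight\tsource_id\n")
        assert read_observations(p) == []

    def test_write_read_identity(self, tmp_path):
        records = [
            ObservationRecord(
                reaction=parse_reaction("A + 2 B = C"),
                value_kind="K_prime",
                value=1.5,
                conditions=thermo.Conditions(T=303.15, pH=6.5, ionic_strength=0.1),
                weight=2.0,
                source_id=f"s{i}",
            )
            for i in range(5)
        ]
        p = tmp_path / "obs.tsv"
        write_observations(p, records, header="fixture")
        back = read_observations(p)
        assert len(back) == 5
        for a, b in zip(records, back):
            assert a.reaction == b.reaction
            assert a.value_kind == b.value_kind
            assert a.value == pytest.approx(b.value)
            assert a.conditions == b.conditions
            assert a.weight == pytest.approx(b.weight)
            assert a.source_id == b.source_id

    def test_defaults_applied_and_errors_carry_line_numbers(self, tmp_path):
        p = tmp_path / "obs.tsv"
        p.write_text(
            "reaction\tvalue_kind\tvalue\tT_K\tpH\tI_M\tweight\tsource_id\n"
            "A = B\tK_prime\t1.0\t\t\t\t\ts\n"
            "A = B\tbogus_kind\t1.0\t\t\t\t\ts\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_observations(p)
        p2 = tmp_path / "ok.tsv"
        p2.write_text(
            "reaction\tvalue_kind\tvalue\tT_K\tpH\tI_M\tweight\tsource_id\n"
            "A = B\tK_prime\t1.0\t\t\t\t\ts\n"
        )
        rec = read_observations(p2)[0]
        assert rec.conditions == thermo.Conditions()  # T=298.15, pH=7, I=0.25
        assert rec.weight == 1.0


class TestStandardize:
    def trivial_db(self, compounds):
        return {
            c: [thermo.SpeciesRecord(c, 0.0, 0, 0, is_reference=True)]
            for c in compounds
        }

    def test_dg_standard_passthrough(self):
        rec = ObservationRecord(
            parse_reaction("A = B"), "dG_standard", -7.5, thermo.Conditions()
        )
        (_, dg0, _, _), = standardize([rec], None)
        assert dg0 == -7.5

    def test_unit_keq_trivial_species(self):
        rec = ObservationRecord(
            parse_reaction("A = B"),
            "K_prime",
            1.0,
            thermo.Conditions(ionic_strength=0.0),
        )
        (_, dg0, _, _), = standardize([rec], self.trivial_db("AB"))
        assert dg0 == pytest.approx(0.0, abs=1e-12)

    def test_protonatable_compound_matches_two_term_oracle(self):
        pka = 6.0
        rt_ln10 = RT * math.log(10)
        db = self.trivial_db("A")
        db["X"] = [
            thermo.SpeciesRecord("X", 0.0, 0, 0, is_reference=True),
            thermo.SpeciesRecord("X", -rt_ln10 * pka, 1, 1),
        ]
        cond = thermo.Conditions(T=298.15, pH=pka, ionic_strength=0.0)
        rec = ObservationRecord(parse_reaction("A = X"), "K_prime", 1.0, cond)
        (_, dg0, _, _), = standardize([rec], db)
        # K'=1 -> dG'=0; correction for X is the two-term log-sum-exp
        g1 = 0.0  # reference species, n_H=0
        g2 = -rt_ln10 * pka + rt_ln10 * pka  # offset + 1 proton at pH=pKa
        corr = -RT * math.log(math.exp(-g1 / RT) + math.exp(-g2 / RT))
        assert dg0 == pytest.approx(0.0 - corr, abs=1e-9)
        assert dg0 == pytest.approx(RT * math.log(2), abs=1e-9)

    def test_missing_species_lists_compounds(self):
        rec = ObservationRecord(
            parse_reaction("A = B"), "K_prime", 2.0, thermo.Conditions()
        )
        with pytest.raises(KeyError, match="B"):
            standardize([rec], {"A": self.trivial_db("A")["A"]})


class TestCanonicalize:
    def test_orientation_antisymmetry(self):
        r = parse_reaction("A + B = 2 C")
        k1, f1 = canonicalize_reaction(r)
        k2, f2 = canonicalize_reaction(-r)
        assert k1 == k2
        assert f1 == -f2

    def test_scaling_merges(self):
        k1, _ = canonicalize_reaction(parse_reaction("2 A = 2 B"))
        k2, _ = canonicalize_reaction(parse_reaction("A = B"))
        assert k1 == k2

    def test_rescaling_factor_scales_value(self):
        _, f = canonicalize_reaction(parse_reaction("2 A = 2 B"))
        assert abs(f) == pytest.approx(0.5)

    def test_idempotent(self, rng):
        for _ in range(20):
            coeffs = {
                f"C{i}": float(rng.integers(-3, 4))
                for i in range(5)
                if rng.random() < 0.7
            }
            coeffs = {k: v for k, v in coeffs.items() if v != 0}
            if not coeffs:
                continue
            r = ReactionVector.from_dict(coeffs)
            k1, _ = canonicalize_reaction(r)
            r2 = ReactionVector.from_dict({c: float(v) for c, v in k1})
            k2, f2 = canonicalize_reaction(r2)
            assert k1 == k2
            assert f2 == 1.0


class TestAggregate:
    def _std(self, triples):
        return [(parse_reaction(f), v, 1.0, "s") for f, v in triples]

    def test_median_of_replicates(self):
        td = aggregate_replicates(
            self._std([("A = B", 1.0), ("A = B", 2.0), ("A = B", 9.0)])
        )
        assert td.n_reactions == 1
        assert td.dG_obs[0] == pytest.approx(2.0)
        assert td.replicate_counts[0] == 3

    def test_single_observation(self):
        td = aggregate_replicates(self._std([("A = B", -4.2)]))
        assert td.dG_obs[0] == pytest.approx(-4.2)

    def test_reverse_replicates_fold_with_sign(self):
        # B = A observed at +3 is the same chemical reaction as A = B at -3
        td = aggregate_replicates(self._std([("A = B", -3.0), ("B = A", 3.0)]))
        assert td.n_reactions == 1
        assert td.dG_obs[0] == pytest.approx(-3.0)
        assert td.replicate_counts[0] == 2

    def test_collapse_counts(self, rng):
        formulas = ["A = B", "B = C", "A = C", "2 A = D", "D = E", "C + A = E", "E = F"]
        rows = []
        for i in range(20):
            f = formulas[i % 7]
            rows.append((f, float(rng.normal())))
        td = aggregate_replicates(self._std(rows))
        assert td.n_reactions == 7
        assert td.replicate_counts.sum() == 20

    def test_row_order_invariance(self, rng):
        rows = [("A = B", 1.0), ("B = C", 5.0), ("A = B", 3.0), ("A = C", 2.0)]
        td1 = aggregate_replicates(self._std(rows))
        td2 = aggregate_replicates(self._std(list(reversed(rows))))
        assert td1.reaction_index == td2.reaction_index
        np.testing.assert_allclose(td1.dG_obs, td2.dG_obs)
        np.testing.assert_allclose(td1.S, td2.S)


class TestProjection:
    def test_consistent_vector_is_fixed_point(self, rng):
        S = rng.integers(-2, 3, size=(6, 4)).astype(float)
        f = rng.normal(size=6)
        td = training_data_from_matrices(S, S.T @ f)
        out = project_observations(td)
        np.testing.assert_allclose(out.dG_obs, td.dG_obs, atol=1e-9)
        assert out.projected_ss == pytest.approx(0.0, abs=1e-16)

    def test_duplicate_columns_average(self):
        # two copies of A -> B with conflicting values a, b: the projection
        # onto the 1-D consistent subspace replaces both by the mean
        S = np.array([[-1.0, -1.0], [1.0, 1.0]])
        a, b = 3.0, 7.0
        td = training_data_from_matrices(S, np.array([a, b]))
        out = project_observations(td)
        np.testing.assert_allclose(out.dG_obs, [(a + b) / 2, (a + b) / 2], atol=1e-12)
        assert out.projected_ss == pytest.approx((a - b) ** 2 / 2)

    def test_idempotent(self, rng):
        S = rng.integers(-2, 3, size=(5, 6)).astype(float)
        td = training_data_from_matrices(S, rng.normal(size=6))
        once = project_observations(td)
        twice = project_observations(once)
        np.testing.assert_allclose(once.dG_obs, twice.dG_obs, atol=1e-12)
        assert twice.projected_ss == pytest.approx(once.projected_ss, abs=1e-12)


def test_pipeline_deterministic(tmp_path, rng):
    """read -> standardize is bit-stable: same file, same output ordering."""
    records = [
        ObservationRecord(
            parse_reaction(f), "dG_standard", v, thermo.Conditions(), source_id=s
        )
        for f, v, s in [("A = B", 1.0, "x"), ("B = C", 2.0, "y"), ("A = B", 1.5, "z")]
    ]
    p = tmp_path / "obs.tsv"
    write_observations(p, records)
    out1 = standardize(read_observations(p), None)
    out2 = standardize(read_observations(p), None)
    assert out1 == out2
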