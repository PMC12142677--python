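"""Database matching, CCS-threshold filtering and isobar adjudication."""

import numpy as np
import pandas as pd
import pytest

from cimccs import annotate as ann
from cimccs import simulate as sim
from cimccs.masscalc import adduct_mz


@pytest.fixture
def toy_db():
    return [
        ann.DatabaseEntry.from_formula("cmpdA", "C24H50NO7P", class_tag="PC(16:0)"),
        ann.DatabaseEntry.from_formula("cmpdB", "C6H12O6"),
    ]


def _entry(mass, name="x"):
    # database entry with an explicit mass (formula-free construction for m/z tests)
    from cimccs.masscalc import ElementalFormula

    return ann.DatabaseEntry(name=name, formula=ElementalFormula(), mass=mass)


class TestDbMatch:
    def test_single_hit_within_5ppm(self):
        hits = ann.db_match(501.0076, [_entry(500.000)], adducts=("[M+H]+",))
        assert len(hits) == 1
        assert hits[0].error == pytest.approx(-0.43, abs=0.05)

    def test_tight_tolerance_excludes(self):
        assert ann.db_match(501.0076, [_entry(500.000)], adducts=("[M+H]+",), tol=0.1) == []

    def test_boundary_is_inclusive(self):
        from cimccs.masscalc import ppm_error

        theo = adduct_mz(500.000, "[M+H]+")
        query = theo * (1 + 5e-6)  # ~ +5 ppm
        realized = abs(ppm_error(query, theo))
        # tolerance set to the realized error itself: inclusive bounds keep it
        hits = ann.db_match(query, [_entry(500.000)], adducts=("[M+H]+",), tol=realized)
        assert len(hits) == 1

    def test_da_mode(self):
        theo = adduct_mz(500.000, "[M+H]+")
        hits = ann.db_match(theo + 0.004, [_entry(500.000)], adducts=("[M+H]+",),
                            tol=0.005, tol_mode="da")
        assert len(hits) == 1 and hits[0].tol_mode == "da"

    def test_row_order_invariance(self):
        entries = [_entry(500.000, "a"), _entry(500.001, "b"), _entry(499.999, "c")]
        fwd = ann.db_match(501.0076, entries, adducts=("[M+H]+",), tol=20)
        rev = ann.db_match(501.0076, entries[::-1], adducts=("[M+H]+",), tol=20)
        assert [m.entry.name for m in fwd] == [m.entry.name for m in rev]

    def test_empty_database_raises(self):
        with pytest.raises(ValueError):
            ann.db_match(500.0, [])


def _cands(diffs):
    return [
        ann.Candidate(rank=i + 1, structure="C" * (i + 1), formula=f"C{i+1}H{2*i+4}",
                      adduct="[M+H]+", percent_diff=d)
        for i, d in enumerate(diffs)
    ]


class TestFilterCandidates:
    def test_empty_list(self):
        res = ann.filter_candidates([])
        assert (len(res.kept), len(res.removed)) == (0, 0)

    def test_mixed_list_partition(self):
        res = ann.filter_candidates(_cands([0.4, -0.5, 2.4, 3.1]), threshold_pct=1.0)
        assert len(res.kept) == 2 and len(res.removed) == 2
        assert all(c.disposition == "kept" for c in res.kept)
        assert all(c.disposition == "removed" for c in res.removed)

    def test_boundary_value_survives(self):
        res = ann.filter_candidates(_cands([1.0]), threshold_pct=1.0)
        assert len(res.kept) == 1

    def test_partition_and_monotonicity_over_random_lists(self):
        for s in range(100):
            rng = np.random.default_rng(s)
            cands = _cands(rng.normal(0, 2.0, size=30))
            t1, t2 = sorted(rng.uniform(0.2, 3.0, size=2))
            r1 = ann.filter_candidates(cands, t1)
            r2 = ann.filter_candidates(cands, t2)
            # partition at every threshold
            assert len(r1.kept) + len(r1.removed) == 30
            assert not set(id(c) for c in r1.kept) & set(id(c) for c in r1.removed)
            # lower threshold removes a superset
            removed1 = {c.rank for c in r1.removed}
            removed2 = {c.rank for c in r2.removed}
            assert removed2 <= removed1

    def test_missing_percent_diff_raises(self):
        c = ann.Candidate(rank=1, structure="C", formula="CH4", adduct="[M+H]+")
        with pytest.raises(ValueError):
            ann.filter_candidates([c])


class TestAdjudication:
    def test_smaller_difference_wins(self):
        adj = ann.adjudicate_isobars(200.0, _cands([0.4, 2.1]))
        assert adj.winner.rank == 1 and not adj.ambiguous

    def test_equal_magnitudes_are_ambiguous(self):
        adj = ann.adjudicate_isobars(200.0, _cands([1.0, -1.0]))
        assert adj.ambiguous and adj.winner is None

    def test_winner_has_minimal_difference(self):
        rng = np.random.default_rng(3)
        cands = _cands(rng.normal(0, 2, 8))
        adj = ann.adjudicate_isobars(200.0, cands)
        if adj.winner is not None:
            assert abs(adj.winner.percent_diff) == min(abs(c.percent_diff) for c in cands)

    def test_recomputes_from_predicted_ccs(self):
        cands = [
            ann.Candidate(rank=1, structure="C", formula="CH4", adduct="[M+Na]+",
                          predicted_ccs=201.0),
            ann.Candidate(rank=2, structure="CC", formula="C2H6", adduct="[M+H]+",
                          predicted_ccs=206.0),
        ]
        adj = ann.adjudicate_isobars(200.0, cands)
        assert adj.winner.adduct == "[M+Na]+"
        assert adj.winner.percent_diff == pytest.approx(0.5)

    def test_single_candidate_raises(self):
        with pytest.raises(ValueError):
            ann.adjudicate_isobars(200.0, _cands([0.4]))

    def test_simulated_pairs_all_resolved_to_truth(self):
        cases, _ = sim.simulate_isobar_pairs(n_pairs=5, seed=9)
        wins = sum(
            ann.adjudicate_isobars(c.experimental_ccs, c.candidates).winner.adduct
            == c.true_adduct
            for c in cases
        )
        assert wins == 5


class TestSumComposition:
    def test_identical_formula_and_adduct_match(self, toy_db):
        c = ann.Candidate(rank=1, structure="C", formula="C24H50NO7P", adduct="[M+H]+")
        assert ann.sum_composition_check(c, (toy_db[0], "[M+H]+"))

    def test_formula_off_by_ch2_fails(self, toy_db):
        c = ann.Candidate(rank=1, structure="C", formula="C25H52NO7P", adduct="[M+H]+")
        assert not ann.sum_composition_check(c, (toy_db[0], "[M+H]+"))

    def test_adduct_mismatch_fails(self, toy_db):
        # same formula annotated as the wrong ion type, e.g. predicted [M+H]+
        # for a feature putatively matched as [M+K]+
        c = ann.Candidate(rank=1, structure="C", formula="C24H50NO7P", adduct="[M+H]+")
        assert not ann.sum_composition_check(c, (toy_db[0], "[M+K]+"))


class TestIngest:
    def _frame(self, n, **overrides):
        df = pd.DataFrame(
            {
                "rank": np.arange(1, n + 1),
                "structure": ["C" * (i + 1) for i in range(n)],
                "formula": [f"C{i+1}H{2*i+4}" for i in range(n)],
                "adduct": "[M+H]+",
                "source": "database",
            }
        )
        for k, v in overrides.items():
            df[k] = v
        return df

    def test_well_formed_file(self, tmp_path):
        path = tmp_path / "cands.csv"
        self._frame(20).to_csv(path, index=False)
        assert len(ann.ingest_candidates(path)) == 20

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "cands.csv"
        self._frame(5).drop(columns=["structure"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="structure"):
            ann.ingest_candidates(path)

    def test_top_k_truncation(self):
        cands = ann.ingest_candidates(self._frame(25), top_k=20)
        assert len(cands) == 20
        assert [c.rank for c in cands] == list(range(1, 21))

    def test_duplicate_ranks_raise(self):
        df = self._frame(5)
        df.loc[1, "rank"] = 1
        with pytest.raises(ValueError, match="duplicate"):
            ann.ingest_candidates(df)

    def test_unparseable_structure_skipped_with_warning(self):
        df = self._frame(5)
        df.loc[2, "structure"] = "C((("
        with pytest.warns(UserWarning, match="unparseable"):
            cands = ann.ingest_candidates(df)
        assert len(cands) == 4


class TestAnnotateFeature:
    def test_composed_report_with_db_hit(self, toy_db):
        mz = adduct_mz(toy_db[0].mass, "[M+H]+")
        cands = [
            ann.Candidate(rank=1, structure="C", formula="C24H50NO7P",
                          adduct="[M+H]+", predicted_ccs=250.5),
            ann.Candidate(rank=2, structure="CC", formula="C24H50NO7P",
                          adduct="[M+H]+", predicted_ccs=251.5),
        ]
        report = ann.annotate_feature(mz, 250.0, toy_db, cands)
        assert report.status == "annotated"
        assert report.n_kept + report.n_removed == report.n_total == 2
        assert report.winner.rank == 1
        assert all(c.sum_match for c in report.kept)

    def test_no_inputs_yields_unknown(self):
        report = ann.annotate_feature(999.9, None, [], [])
        assert report.status == "unknown"
        assert report.n_total == 0

    def test_planted_truth_recovered_across_seeds(self):
        hits = 0
        for s in range(100):
            cands, truth = sim.simulate_candidates(
                n_database=3, n_de_novo=17, experimental_ccs=250.0, seed=s
            )
            report = ann.annotate_feature(500.0, 250.0, [], cands)
            if report.winner is not None and report.winner.rank == 1:
                hits += 1
        assert hits >= 95

    def test_threshold_monotonicity_in_report(self):
        cands, _ = sim.simulate_candidates(
            n_database=8, n_de_novo=100,
            band_counts=[(1.0, 5.0, 78), (0.5, 1.0, 13), (0.0, 0.5, 17)], seed=4,
        )
        r1 = ann.filter_candidates(cands, 1.0)
        r05 = ann.filter_candidates(cands, 0.5)
        assert {c.rank for c in r1.removed} <= {c.rank for c in r05.removed}


class TestLoadDatabase:
    def test_load_and_mass_check(self, tmp_path):
        path = tmp_path / "db.csv"
        pd.DataFrame(
            {"name": ["glucose"], "formula": ["C6H12O6"], "class": ["sugar"]}
        ).to_csv(path, index=False)
        db = ann.load_database(path)
        assert db[0].mass == pytest.approx(180.0634, abs=1e-3)

    def test_inconsistent_mass_raises(self, tmp_path):
        path = tmp_path / "db.csv"
        pd.DataFrame(
            {"name": ["glucose"], "formula": ["C6H12O6"], "mass": [181.0]}
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="disagrees"):
            ann.load_database(path)
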