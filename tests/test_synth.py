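import numpy as np
import pandas as pd
import pytest

from herbnet import synth
from herbnet.io import Role
from herbnet.role_sets import venn7
from herbnet.stats import AnnotationCollection, hypergeom_enrich


class TestDeterminism:
    def test_same_seed_gives_identical_bundles(self, tmp_path):
        a = synth.generate(synth.SyntheticConfig(seed=13))
        b = synth.generate(synth.SyntheticConfig(seed=13))
        pd.testing.assert_frame_equal(a.formulary, b.formulary)
        pd.testing.assert_frame_equal(a.assoc, b.assoc)
        pd.testing.assert_frame_equal(a.ppi, b.ppi)
        pd.testing.assert_frame_equal(a.annotation, b.annotation)
        pd.testing.assert_frame_equal(a.docking, b.docking)
        assert a.hub_lists == b.hub_lists

    def test_written_bundle_is_byte_identical(self, tmp_path):
        cfg = synth.SyntheticConfig(seed=13)
        p1 = synth.write_bundle(synth.generate(cfg), tmp_path / "a")
        p2 = synth.write_bundle(synth.generate(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_different_seeds_differ(self):
        a = synth.generate(synth.SyntheticConfig(seed=1))
        b = synth.generate(synth.SyntheticConfig(seed=2))
        assert not a.formulary.equals(b.formulary)


class TestFormulary:
    def test_role_structure(self):
        herbs, _, _ = synth.gen_formulary(synth.SyntheticConfig(seed=0))
        per_role = {r: sum(1 for h in herbs if h.role is r) for r in Role}
        assert per_role == {Role.JUN: 2, Role.CHEN: 3, Role.ZUO_SHI: 6}

    def test_zero_multi_role_fraction_empties_venn_intersections(self):
        cfg = synth.SyntheticConfig(seed=3, multi_role_fraction=0.0)
        herbs, compounds, _ = synth.gen_formulary(cfg)
        role_of = {h.name: h.role for h in herbs}
        sets = {r: set() for r in Role}
        for c in compounds.values():
            for h in c.herbs:
                sets[role_of[h]].add(c.id)
        dec = venn7(sets[Role.JUN], sets[Role.CHEN], sets[Role.ZUO_SHI])
        assert all(
            not dec.regions[r]
            for r in dec.regions
            if "∩" in r
        )

    def test_jun_ob_shift_recovered(self):
        """Mean Jun-vs-Chen OB difference over replicates recovers the
        planted +8 shift within +-1.5 at 500 compounds per draw."""
        diffs = []
        for seed in range(20):
            cfg = synth.SyntheticConfig(seed=seed, n_compounds=500)
            herbs, compounds, _ = synth.gen_formulary(cfg)
            role_of = {h.name: h.role for h in herbs}
            ob = {r: [] for r in Role}
            for c in compounds.values():
                for r in {role_of[h] for h in c.herbs}:
                    ob[r].append(c.OB)
            diffs.append(np.mean(ob[Role.JUN]) - np.mean(ob[Role.CHEN]))
        assert abs(np.mean(diffs) - 8.0) < 1.5


class TestAssoc:
    def test_heavy_tailed_out_degree(self):
        """Max compound degree dominates the median in >=90% of seeds."""
        wins = 0
        for seed in range(20):
            cfg = synth.SyntheticConfig(seed=seed, n_compounds=200)
            _, compounds, _ = synth.gen_formulary(cfg)
            targets = synth.gen_targets(cfg)
            assoc = synth.gen_assoc(cfg, compounds, targets)
            deg = assoc.groupby("compound_id").size()
            if deg.max() >= 10 * deg.median():
                wins += 1
        assert wins >= 18

    def test_large_exponent_gives_near_uniform_low_degrees(self):
        cfg = synth.SyntheticConfig(seed=5, assoc_exponent=50.0)
        _, compounds, _ = synth.gen_formulary(cfg)
        assoc = synth.gen_assoc(cfg, compounds, synth.gen_targets(cfg))
        deg = assoc.groupby("compound_id").size()
        assert deg.max() <= 3

    def test_no_duplicate_pairs(self):
        cfg = synth.SyntheticConfig(seed=6)
        _, compounds, _ = synth.gen_formulary(cfg)
        assoc = synth.gen_assoc(cfg, compounds, synth.gen_targets(cfg))
        assert not assoc.duplicated(["compound_id", "target"]).any()


class TestPpi:
    def test_attachment_one_gives_tree(self):
        cfg = synth.SyntheticConfig(seed=7, ppi_n=80, ppi_m=1)
        ppi, _ = synth.gen_ppi(cfg)
        assert len(ppi) == 79  # edges = nodes - 1

    def test_default_scale_matches_dense_interactome(self):
        cfg = synth.SyntheticConfig(seed=7)
        ppi, _ = synth.gen_ppi(cfg)
        # m*(n-m) = 12 * 488
        assert len(ppi) == 5856

    def test_confidence_range(self):
        ppi, _ = synth.gen_ppi(synth.SyntheticConfig(seed=8))
        assert ppi["confidence"].between(0.15, 1.0).all()


class TestAnnotations:
    def test_planted_term_detected_at_default_odds(self):
        b = synth.generate(synth.SyntheticConfig(seed=9))
        ann = AnnotationCollection.from_edges(b.annotation)
        query = set(b.disease_targets) & set(ann.universe)
        res = hypergeom_enrich(query, ann)
        assert res.iloc[0]["term"] == "PLANTED"
        assert res.iloc[0]["fdr"] < 0.05

    def test_unit_odds_is_null(self):
        """With odds=1 the planted term behaves like background."""
        firsts = 0
        for seed in range(30):
            cfg = synth.SyntheticConfig(seed=seed, planted_odds=1.0)
            b = synth.generate(cfg)
            ann = AnnotationCollection.from_edges(b.annotation)
            query = set(b.disease_targets) & set(ann.universe)
            res = hypergeom_enrich(query, ann)
            if res.iloc[0]["term"] == "PLANTED":
                firsts += 1
        # ~1/30 chance per seed of ranking first; allow generous slack
        assert firsts <= 8
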