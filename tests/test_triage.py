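"""Decision-tree filters, zygosity resolution and end-to-end triage."""

import numpy as np
import pytest

from neoscreen import synth
from neoscreen.genomic_io import VariantCall
from neoscreen.intervals import IntervalSet
from neoscreen.knowledge import KnowledgeBase, Panel, PanelGene
from neoscreen.triage import (
    SampleMeta,
    TriageConfig,
    default_par,
    filter_frequency,
    filter_panel,
    filter_quality,
    resolve_zygosity,
    run_decision_tree,
    _Annotated,
)


def call(chrom="1", pos=1000, ref="A", alt="G", genotype="het", depth=100,
         qd=15.0, sample="S1"):
    ad = depth if genotype != "het" else depth // 2
    return VariantCall(chrom, pos, ref, alt, genotype, depth, (depth - ad, ad),
                       qd, sample)


def tiny_panel():
    g1 = PanelGene("G1", "AR", IntervalSet.from_tuples([("1", 900, 1200)]))
    g2 = PanelGene("G2", "AD", IntervalSet.from_tuples([("2", 100, 400)]))
    gx = PanelGene("GX", "XL", IntervalSet.from_tuples([("X", 5_000_000, 5_001_000)]))
    return Panel("v1", {"G1": g1, "G2": g2, "GX": gx})


class TestFilters:
    def test_panel_annotation_and_drop(self):
        panel = tiny_panel()
        kept, audit = filter_panel([call(pos=1000), call(pos=5000)], panel)
        assert [av.genes for av in kept] == [("G1",)]
        assert audit[0].reason == "off-panel" and not audit[0].kept

    def test_ambiguous_gene_assignment_flagged(self):
        overlap = PanelGene("G1b", "AD", IntervalSet.from_tuples([("1", 950, 1100)]))
        panel = tiny_panel()
        panel.genes["G1b"] = overlap
        kept, audit = filter_panel([call(pos=1000)], panel)
        assert kept[0].genes == ("G1", "G1b")
        assert any(a.reason == "ambiguous-gene" and a.kept for a in audit)

    @pytest.mark.parametrize(
        "depth,qd,reason",
        [(29, 15.0, "low-depth"), (40, None, "no-QD"), (None, 15.0, "no-DP"),
         (40, 1.5, "low-QD")],
    )
    def test_quality_drops(self, depth, qd, reason):
        v = VariantCall("1", 1000, "A", "G", "het", depth, None, qd, "S1")
        kept, audit = filter_quality([_Annotated(v, ("G1",))], 30, 2.0)
        assert not kept and audit[0].reason == reason

    def test_quality_boundary_passes(self):
        kept, _ = filter_quality([_Annotated(call(depth=30, qd=2.0), ("G1",))], 30, 2.0)
        assert len(kept) == 1

    def test_frequency_common_dropped_unless_frequent_gene(self):
        panel = tiny_panel()
        kb = KnowledgeBase()
        v = call(pos=1000)
        kb.add_frequency(v.key, 0.02)
        kept, audit = filter_frequency([_Annotated(v, ("G1",))], panel, kb, 0.01)
        assert not kept and "common" in audit[0].reason
        panel.genes["G1"].frequent_gene = True
        kept, _ = filter_frequency([_Annotated(v, ("G1",))], panel, kb, 0.01)
        assert len(kept) == 1

    def test_no_frequency_record_is_rare(self):
        kept, _ = filter_frequency(
            [_Annotated(call(), ("G1",))], tiny_panel(), KnowledgeBase(), 0.01
        )
        assert len(kept) == 1


class TestZygosity:
    def meta(self, sex="female"):
        return SampleMeta("S1", sex=sex)

    def test_ar_single_het_is_unreported_carrier(self):
        gene = tiny_panel().genes["G1"]
        assert resolve_zygosity([call()], gene, self.meta(), default_par()) == []

    def test_ar_homozygote_reported(self):
        gene = tiny_panel().genes["G1"]
        (e,) = resolve_zygosity([call(genotype="hom_alt")], gene, self.meta(),
                                default_par())
        assert e.mechanism == "homozygous" and len(e.variants) == 1

    def test_ar_two_distinct_hets_form_compound_event(self):
        gene = tiny_panel().genes["G1"]
        vs = [call(pos=1000), call(pos=1050, ref="C", alt="T")]
        (e,) = resolve_zygosity(vs, gene, self.meta(), default_par())
        assert e.mechanism == "possible_compound_het" and len(e.variants) == 2

    def test_carrier_suppression_removing_one_variant_removes_event(self):
        gene = tiny_panel().genes["G1"]
        vs = [call(pos=1000), call(pos=1050, ref="C", alt="T")]
        assert len(resolve_zygosity(vs, gene, self.meta(), default_par())) == 1
        assert resolve_zygosity(vs[:1], gene, self.meta(), default_par()) == []

    def test_ad_single_het_reported(self):
        gene = tiny_panel().genes["G2"]
        (e,) = resolve_zygosity([call(chrom="2", pos=200)], gene, self.meta(),
                                default_par())
        assert e.mechanism == "dominant_het"

    def test_xl_male_het_called_becomes_hemizygous(self):
        gene = tiny_panel().genes["GX"]
        (e,) = resolve_zygosity([call(chrom="X", pos=5_000_500)], gene,
                                self.meta("male"), default_par())
        assert e.mechanism == "hemizygous"

    def test_xl_male_par_variant_follows_diploid_rules(self):
        gene = PanelGene("GP", "XL", IntervalSet.from_tuples([("X", 60000, 70000)]))
        vs = [call(chrom="X", pos=61_000)]
        assert resolve_zygosity(vs, gene, self.meta("male"), default_par()) == []

    def test_xl_female_follows_recessive_rules(self):
        gene = tiny_panel().genes["GX"]
        assert resolve_zygosity([call(chrom="X", pos=5_000_500)], gene,
                                self.meta("female"), default_par()) == []
        (e,) = resolve_zygosity([call(chrom="X", pos=5_000_500, genotype="hom_alt")],
                                gene, self.meta("female"), default_par())
        assert e.mechanism == "homozygous"

    def test_xl_unknown_sex_fails_open_to_review(self):
        gene = tiny_panel().genes["GX"]
        (e,) = resolve_zygosity([call(chrom="X", pos=5_000_500)], gene,
                                self.meta("unknown"), default_par())
        assert e.mechanism is None


class TestDecisionTree:
    def run_scenario(self, panel, ledger, kb, scenario, gene, seed=5):
        spec = synth.ScenarioSpec(scenario, gene, f"T-{scenario}", seed=seed)
        bundle = synth.make_sample(panel, ledger, spec)
        result = run_decision_tree(bundle.calls, panel, kb, bundle.meta)
        return bundle, result

    @pytest.mark.parametrize("scenario,gene_role", [
        ("negative", "SERPINA1"), ("carrier_AR", "SERPINA1"), ("hom_AR", "ALDOB"),
        ("compound_het_AR", "SERPINA1"), ("dominant_AD", "ELN"),
        ("hemi_XL_male", "OTC"), ("xl_female_comp_het", "OTC"),
        ("vus_only", "ALDOB"), ("conflicting", "SERPINA1"),
        ("off_panel", "SERPINA1"), ("low_depth", "PAH"),
    ])
    def test_scenarios_reproduce_ground_truth(self, panel, kb, ledger, scenario,
                                              gene_role):
        bundle, result = self.run_scenario(panel, ledger, kb, scenario, gene_role)
        assert result.status == bundle.expected_status
        got = [{"gene": e.gene, "mechanism": e.mechanism,
                "n_variants": len(e.variants)} for e in result.events]
        assert got == bundle.expected_events

    def test_auto_closed_iff_no_events(self, panel, kb, ledger):
        for scenario, gene in synth.default_scenario_plan(panel):
            _, result = self.run_scenario(panel, ledger, kb, scenario, gene)
            assert (result.status == "auto_closed") == (not result.events)

    def test_empty_sample_auto_closes(self, panel, kb):
        result = run_decision_tree([], panel, kb, SampleMeta("S0"))
        assert result.status == "auto_closed" and not result.audit

    def test_vus_retained_but_never_reported(self, panel, kb, ledger):
        bundle, result = self.run_scenario(panel, ledger, kb, "vus_only", "ALDOB")
        assert len(result.vus_store) == 1
        assert result.events == []

    def test_every_variant_audited_once_at_terminal_stage(self, panel, kb, ledger):
        bundle, result = self.run_scenario(panel, ledger, kb, "compound_het_AR",
                                           "SERPINA1")
        terminal = [a for a in result.audit if a.reason != "ambiguous-gene"]
        assert sorted(a.key for a in terminal) == sorted(v.key for v in bundle.calls)

    def test_audit_is_deterministic(self, panel, kb, ledger):
        _, r1 = self.run_scenario(panel, ledger, kb, "compound_het_AR", "SERPINA1")
        _, r2 = self.run_scenario(panel, ledger, kb, "compound_het_AR", "SERPINA1")
        assert [a.as_row() for a in r1.audit] == [a.as_row() for a in r2.audit]

    def test_filter_order_invariance_of_event_set(self, panel, kb, ledger):
        # conjunctive filters: frequency-before-quality gives the same events
        spec = synth.ScenarioSpec("hom_AR", "SERPINA1", "T-order", seed=9)
        bundle = synth.make_sample(panel, ledger, spec)
        cfg = TriageConfig()
        annotated, _ = filter_panel(sorted(bundle.calls, key=lambda v: v.key), panel)
        a_then_b, _ = filter_quality(annotated, cfg.dp_min, cfg.qd_min)
        a_then_b, _ = filter_frequency(a_then_b, panel, kb, cfg.af_max)
        b_then_a, _ = filter_frequency(annotated, panel, kb, cfg.af_max)
        b_then_a, _ = filter_quality(b_then_a, cfg.dp_min, cfg.qd_min)
        keys = lambda avs: sorted(av.call.key for av in avs)
        assert keys(a_then_b) == keys(b_then_a)

    def test_no_event_contains_unreportable_variant(self, panel, kb, ledger):
        """Randomized samples: events only ever contain consensus-reportable
        variants, never VUS / benign / conflicting / unknown ones."""
        from neoscreen.knowledge import REPORTABLE_P_LP

        rng = np.random.default_rng(2024)
        genes = sorted(panel.genes)
        for i in range(25):
            scenario = synth.SCENARIOS[int(rng.integers(0, len(synth.SCENARIOS)))]
            need = synth._SCENARIO_INHERITANCE.get(scenario)
            pool = [g for g in genes if need is None
                    or panel.genes[g].inheritance == need]
            spec = synth.ScenarioSpec(scenario, pool[int(rng.integers(0, len(pool)))],
                                      f"R{i}", seed=int(rng.integers(0, 2**30)))
            bundle = synth.make_sample(panel, ledger, spec)
            result = run_decision_tree(bundle.calls, panel, kb, bundle.meta)
            for event in result.events:
                for v in event.variants:
                    assert kb.classify(v).consensus == REPORTABLE_P_LP
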