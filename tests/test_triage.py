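import inspect
import warnings

import numpy as np
import pandas as pd
import pytest

from otutriage import (
    AbundanceTable,
    TriageRecord,
    combined_correlation,
    consensus_classify,
    cured_sick_screen,
    dilution_adjust,
    harmonized_average,
    marker_correlation_panel,
    stratify_extremes,
    triage_study,
)
from otutriage.config import PipelineConfig
from otutriage.diffabund import DifferentialResult, differential_otus
from otutriage.pathology import MARKER_DIRECTIONS, MARKER_NAMES
from otutriage.simulate import SimulationConfig, generate_markers, make_study
from otutriage.triage import ExtremeGroups, pearson_fit


def _dko_table(values: dict, index) -> AbundanceTable:
    data = pd.DataFrame(values, index=index)
    meta = pd.DataFrame(
        {"genotype": "DKO", "treatment": "splenda", "sex": "M"}, index=index
    )
    return AbundanceTable(data, meta)


class TestStratifyExtremes:
    def test_threshold_application(self):
        scores = {"a": 0.5, "b": 1.0, "c": 3.0, "d": 5.0, "e": 8.0}
        g = stratify_extremes(scores)
        assert set(g.cured_ids) == {"a", "b"}
        assert set(g.sick_ids) == {"d", "e"}

    def test_intermediate_scores_empty_groups_warn(self):
        with pytest.warns(UserWarning, match="0 cured"):
            g = stratify_extremes({"a": 3.0, "b": 3.0})
        assert g.cured_ids == () and g.sick_ids == ()

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            ExtremeGroups(("a",), ("a", "b"))
        with pytest.raises(ValueError, match="below"):
            stratify_extremes({}, cured_max=5, sick_min=5)


class TestCuredSickScreen:
    def test_ratio_and_direction(self):
        idx = [f"m{i}" for i in range(8)]
        t = _dko_table({"X": [2, 2, 2, 2, 8, 8, 8, 8], "Y": [9, 9, 9, 9, 3, 3, 3, 3]}, idx)
        groups = ExtremeGroups(tuple(idx[:4]), tuple(idx[4:]))
        out = cured_sick_screen(t, groups)
        assert out.loc["X", "ratio_cured_over_sick"] == pytest.approx(0.25)
        assert out.loc["X", "direction"] == "provocative"
        assert out.loc["Y", "direction"] == "beneficial_or_opportunistic"

    def test_floor_applies_to_trace_means(self):
        idx = [f"m{i}" for i in range(4)]
        t = _dko_table({"X": [0.0, 0.0, 1.0, 1.0]}, idx)
        out = cured_sick_screen(t, ExtremeGroups(tuple(idx[:2]), tuple(idx[2:])), floor=0.1)
        assert out.loc["X", "ratio_cured_over_sick"] == pytest.approx(0.1)

    def test_empty_group_rejected(self, group_mean_fixture_table):
        with pytest.raises(ValueError, match="non-empty"):
            cured_sick_screen(group_mean_fixture_table, ExtremeGroups((), ("x",)))

    def test_null_pvalues_roughly_uniform(self, rng):
        """Identical cured/sick distributions give ratio ~ 1 and ~5% hits."""
        hits, ratios = 0, []
        for _ in range(200):
            idx = [f"m{i}" for i in range(16)]
            t = _dko_table({"X": rng.normal(5, 1, size=16).clip(0)}, idx)
            out = cured_sick_screen(t, ExtremeGroups(tuple(idx[:8]), tuple(idx[8:])))
            hits += out.loc["X", "p_value"] <= 0.05
            ratios.append(out.loc["X", "ratio_cured_over_sick"])
        assert hits / 200 <= 0.12
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_candidate_family_adjustment(self):
        rng = np.random.default_rng(3)
        idx = [f"m{i}" for i in range(12)]
        vals = {
            "strong": np.r_[rng.normal(1, 0.2, 6), rng.normal(6, 0.2, 6)],
            "null1": rng.uniform(2, 3, 12),
            "null2": rng.uniform(2, 3, 12),
        }
        t = _dko_table(vals, idx)
        out = cured_sick_screen(t, ExtremeGroups(tuple(idx[:6]), tuple(idx[6:])))
        # the candidate family here is {strong} alone -> Bonferroni factor 1
        assert out.loc["strong", "adjusted_p"] == pytest.approx(out.loc["strong", "p_value"])
        out_all = cured_sick_screen(
            t, ExtremeGroups(tuple(idx[:6]), tuple(idx[6:])), family="all"
        )
        assert out_all.loc["strong", "adjusted_p"] == pytest.approx(
            min(out.loc["strong", "p_value"] * 3, 1.0)
        )


class TestCorrelationPanel:
    def test_abundance_equal_to_score_gives_r_one(self):
        idx = [f"m{i}" for i in range(6)]
        score = np.array([0.5, 1, 2, 4, 6, 8])
        t = _dko_table({"X": score.copy()}, idx)
        markers = pd.DataFrame(
            {
                "overall_score": score,
                "exfoliation_fraction": np.linspace(0, 0.5, 6),
                "paneth_fraction": np.linspace(0.9, 0.1, 6),
                "abscesses_per_field": np.linspace(0, 2, 6),
                "apoptosis_per_crypt": np.linspace(0, 0.4, 6),
            },
            index=idx,
        )
        panel = marker_correlation_panel(t, markers)
        assert panel.loc["X", "overall_score"] == pytest.approx(1.0)
        assert not panel.loc["X", "overall_score_degenerate"]

    def test_constant_abundance_flagged_degenerate(self):
        idx = [f"m{i}" for i in range(5)]
        t = _dko_table({"X": [2.0] * 5}, idx)
        markers = pd.DataFrame(
            {name: np.linspace(0, 1, 5) for name in MARKER_NAMES}, index=idx
        )
        panel = marker_correlation_panel(t, markers)
        assert panel.loc["X", "overall_score"] == 0.0
        assert bool(panel.loc["X", "overall_score_degenerate"])

    def test_noisy_linear_link_recovered(self, rng):
        idx = [f"m{i}" for i in range(30)]
        abundance = rng.uniform(0, 60, 30)
        score = 0.1 * abundance + rng.normal(0, 0.3, 30)
        t = _dko_table({"X": abundance}, idx)
        markers = pd.DataFrame({name: score for name in MARKER_NAMES}, index=idx)
        panel = marker_correlation_panel(t, markers)
        assert panel.loc["X", "overall_score"] > 0.95


class TestHarmonizedAverage:
    def test_paneth_sign_flip(self):
        r = {
            "overall_score": 0.5,
            "exfoliation_fraction": 0.5,
            "paneth_fraction": -0.5,
            "abscesses_per_field": 0.5,
            "apoptosis_per_crypt": 0.5,
        }
        assert harmonized_average(r) == pytest.approx(0.5)

    def test_all_zero(self):
        assert harmonized_average({name: 0.0 for name in MARKER_NAMES}) == 0.0

    def test_antisymmetric_under_global_flip(self, rng):
        for _ in range(100):
            r = {name: float(rng.uniform(-1, 1)) for name in MARKER_NAMES}
            flipped = {k: -v for k, v in r.items()}
            assert harmonized_average(flipped) == pytest.approx(-harmonized_average(r))

    def test_missing_marker_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            harmonized_average({"overall_score": 0.5})

    def test_sign_convention_on_generated_markers(self):
        """Higher provocative abundance -> higher score, lower Paneth fraction:
        every marker contributes positively after harmonization."""
        cfg = SimulationConfig(sigma=0.0, seed=11)
        study = make_study(cfg)
        dko = study.table.dko_samples()
        panel = marker_correlation_panel(dko, study.markers)
        combined = dko.data[list(cfg.provocative_otus)].sum(axis=1)
        rs = {
            name: pearson_fit(combined, study.markers.loc[dko.data.index, name]).r
            for name in MARKER_NAMES
        }
        for name, higher_is_worse in MARKER_DIRECTIONS.items():
            contribution = rs[name] if higher_is_worse else -rs[name]
            assert contribution > 0.5, name
        assert harmonized_average(rs) > 0.5
        del panel


class TestCombinedCorrelation:
    def test_single_otu_reduces_to_panel_entry(self):
        idx = [f"m{i}" for i in range(8)]
        rng = np.random.default_rng(5)
        t = _dko_table({"X": rng.uniform(0, 50, 8), "Y": rng.uniform(0, 5, 8)}, idx)
        score = pd.Series(rng.uniform(0, 8, 8), index=idx)
        markers = pd.DataFrame({name: score for name in MARKER_NAMES}, index=idx)
        panel = marker_correlation_panel(t, markers)
        single = combined_correlation(t, ["X"], score)
        assert single.r == panel.loc["X", "overall_score"]
        assert single.r_squared == pytest.approx(single.r**2, abs=1e-12)

    def test_anticorrelated_pair_is_degenerate(self):
        idx = [f"m{i}" for i in range(5)]
        x = np.array([1.0, 2, 3, 4, 5])
        t = _dko_table({"X": x, "Y": 10 - x}, idx)
        score = pd.Series(np.arange(5.0), index=idx)
        res = combined_correlation(t, ["X", "Y"], score)
        assert res.degenerate
        assert res.r == 0.0

    def test_unknown_otu_rejected(self, group_mean_fixture_table):
        with pytest.raises(ValueError, match="unknown OTUs"):
            combined_correlation(
                group_mean_fixture_table, ["NotAnOtu"], pd.Series(dtype=float)
            )


class TestDilutionAdjust:
    def test_identity_without_diluter(self):
        assert dilution_adjust(40.0, 0.0) == 40.0

    def test_renormalization(self):
        assert dilution_adjust(40.0, 20.0) == pytest.approx(50.0)

    def test_full_dilution_rejected(self):
        with pytest.raises(ValueError):
            dilution_adjust(1.0, 100.0)


class TestConsensusClassify:
    def _record(self, **kw) -> TriageRecord:
        rec = TriageRecord(otu_id="X")
        for k, v in kw.items():
            setattr(rec, k, v)
        return rec

    def _dko_result(self, l2fc, q):
        return DifferentialResult("X", l2fc, 0.0, 0.01, q, True)

    def test_concordant_positive_signals_are_provocative(self):
        rec = self._record(ratio_cured_over_sick=0.3, pairwise_p=0.01, harmonized_mean_r=0.5)
        verdicts = consensus_classify([rec], [self._dko_result(2.0, 0.01)])
        assert verdicts["X"] == "provocative"

    def test_two_negative_signals_are_beneficial(self):
        rec = self._record(ratio_cured_over_sick=1.8, harmonized_mean_r=-0.3)
        assert consensus_classify([rec])["X"] == "beneficial_or_opportunistic"

    def test_genotype_expansion_alone_is_not_provocative(self):
        """A DKO-enriched OTU without pathology-linked evidence stays indeterminate
        (pathology itself reshapes the community)."""
        rec = self._record(harmonized_mean_r=0.1, ratio_cured_over_sick=1.0)
        verdicts = consensus_classify([rec], [self._dko_result(3.0, 0.001)])
        assert verdicts["X"] == "indeterminate"

    def test_weak_correlation_blocks_provocative(self):
        rec = self._record(ratio_cured_over_sick=0.3, pairwise_p=0.01, harmonized_mean_r=0.2)
        assert consensus_classify([rec])["X"] == "indeterminate"

    def test_contraction_plus_negative_correlation_is_beneficial(self):
        rec = self._record(harmonized_mean_r=-0.4)
        verdicts = consensus_classify([rec], [self._dko_result(-2.0, 0.01)])
        assert verdicts["X"] == "beneficial_or_opportunistic"

    def test_designated_provocative_otu_recovered(self):
        """A single planted pathology-driving OTU is labelled provocative in
        >= 90% of replicates."""
        hits = 0
        reps = 100
        for rep in range(reps):
            cfg = SimulationConfig(
                provocative_otus=("Lactobacillus",), beta1=0.11, beta0=1.0,
                sigma=0.8, seed=50_000 + rep,
            )
            study = make_study(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                records = triage_study(study.table, study.markers)
            hits += records["Lactobacillus"].verdict == "provocative"
        assert hits / reps >= 0.90


class TestCrossModuleConsistency:
    def test_shared_floor_default(self):
        """The cured/sick ratio and the differential screen share one floor."""
        cfg = PipelineConfig()
        assert inspect.signature(cured_sick_screen).parameters["floor"].default == cfg.floor
        assert inspect.signature(differential_otus).parameters["floor"].default == cfg.floor

    def test_screen_ratio_uses_same_floor_as_diffabund_means(self):
        idx = [f"m{i}" for i in range(4)]
        t = _dko_table({"X": [0.02, 0.04, 4.0, 6.0]}, idx)
        groups = ExtremeGroups(tuple(idx[:2]), tuple(idx[2:]))
        out = cured_sick_screen(t, groups, floor=0.25)
        assert out.loc["X", "ratio_cured_over_sick"] == pytest.approx(0.25 / 5.0)
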