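import numpy as np
import pandas as pd
import pytest

from msconnectome.connectome import threshold_graph
from msconnectome.graph_metrics import node_degree
from msconnectome.group_stats import (
    NodeMetricLMM,
    build_metric_table,
    fit_all_nodes,
    fit_node_lmm,
    posthoc_contrasts,
)
from msconnectome.synthetic_data import CohortConfig, GroupSpec, generate_cohort


def _simulate_lmm(rng, n_subjects=40, n_sessions=3, beta_group=0.0,
                  beta_session=0.0, subject_sd=0.5, noise_sd=1.0,
                  n_groups=2) -> pd.DataFrame:
    subs = np.repeat(np.arange(n_subjects), n_sessions)
    groups = np.array([f"G{i % n_groups}" for i in range(n_subjects)])[subs]
    sessions = np.tile(np.arange(n_sessions), n_subjects)
    intercepts = rng.normal(0, subject_sd, n_subjects)[subs]
    group_idx = np.array([int(g[1:]) for g in groups])
    value = (1.0 + beta_group * group_idx + beta_session * sessions
             + intercepts + rng.normal(0, noise_sd, subs.size))
    return pd.DataFrame({"subject_id": subs.astype(str), "group": groups,
                         "session": sessions, "value": value})


class TestMetricTable:
    def test_row_count(self):
        config = CohortConfig(
            n_nodes=3,
            groups=(GroupSpec("A", 2, 2, 0.0),),
            base_density=1.0, seed=0,
        )
        cohort = generate_cohort(config)  # 2 subjects x 2 sessions
        table = build_metric_table(cohort, tau=1.0)
        assert len(table) == 2 * 2 * 3 * 4 * 2

    def test_values_match_direct_metric_calls(self):
        config = CohortConfig(n_nodes=10, groups=(GroupSpec("A", 2, 1, 0.0),), seed=1)
        cohort = generate_cohort(config)
        table = build_metric_table(cohort, tau=0.5)
        rec = cohort[0]
        expected = node_degree(threshold_graph(rec.matrix, 0.5), weighted=True).values
        got = table[(table.subject_id == rec.subject_id) & (table.session == 0)
                    & (table.metric == "degree") & table.weighted]
        assert np.allclose(got.sort_values("node")["value"].to_numpy(), expected)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            build_metric_table([], tau=0.35)


class TestNodeLMM:
    def test_noiseless_exact_recovery(self):
        rows = []
        for gi, g in enumerate(["A", "B"]):
            for s in range(4):
                for t in range(3):
                    rows.append((f"{g}{s}", g, t, 1.5 + 2.0 * gi + 0.5 * t))
        df = pd.DataFrame(rows, columns=["subject_id", "group", "session", "value"])
        fit = fit_node_lmm(df)
        assert fit.intercept == pytest.approx(1.5, abs=1e-6)
        assert fit.group_effects["B"] == pytest.approx(2.0, abs=1e-6)
        assert fit.session_effect == pytest.approx(0.5, abs=1e-6)

    def test_parameter_recovery_with_noise(self):
        rng = np.random.default_rng(42)
        estimates = [fit_node_lmm(_simulate_lmm(rng, beta_group=2.0)).group_effects["G1"]
                     for _ in range(60)]
        assert np.mean(estimates) == pytest.approx(2.0, rel=0.1)

    def test_random_intercept_variance_detected(self):
        rng = np.random.default_rng(3)
        fit = fit_node_lmm(_simulate_lmm(rng, n_subjects=120, subject_sd=1.0,
                                         noise_sd=0.5))
        assert 0.5 < fit.random_intercept_var < 2.0
        assert 0.1 < fit.residual_var < 0.6

    def test_reference_group_configurable(self):
        rng = np.random.default_rng(4)
        df = _simulate_lmm(rng, beta_group=1.0)
        fit_a = fit_node_lmm(df, reference="G0")
        fit_b = fit_node_lmm(df, reference="G1")
        assert fit_a.group_effects["G1"] == pytest.approx(-fit_b.group_effects["G0"])

    def test_insufficient_groups_rejected(self):
        rng = np.random.default_rng(5)
        df = _simulate_lmm(rng, n_groups=1)
        with pytest.raises(ValueError, match="2 groups"):
            NodeMetricLMM(df)


class TestPosthocContrasts:
    def test_two_groups_reduce_to_phenotype_coefficient(self):
        rng = np.random.default_rng(6)
        fit = fit_node_lmm(_simulate_lmm(rng, beta_group=2.0))
        contrasts = posthoc_contrasts(fit, force=True)
        assert len(contrasts) == 1
        est = contrasts.iloc[0]
        assert abs(est["estimate"]) == pytest.approx(abs(fit.group_effects["G1"]))

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        fit = fit_node_lmm(_simulate_lmm(rng, beta_group=1.0, n_groups=3),
                           reference="G0")
        contrasts = posthoc_contrasts(fit, force=True)
        lookup = {(r.group_a, r.group_b): r.estimate for r in contrasts.itertuples()}
        assert lookup[("G0", "G1")] == pytest.approx(-(
            fit.group_effects["G1"]))
        assert len(contrasts) == 3  # all unordered pairs

    def test_gated_on_omnibus_significance(self):
        rng = np.random.default_rng(8)
        fit = fit_node_lmm(_simulate_lmm(rng, beta_group=0.0, n_subjects=20))
        if fit.group_omnibus_pvalue >= 0.05:
            assert posthoc_contrasts(fit).empty
        assert not posthoc_contrasts(fit, force=True).empty

    def test_null_contrast_rate_bounded(self):
        """Adjusted significant-contrast rate stays at or below nominal alpha."""
        rng = np.random.default_rng(9)
        n_sig = 0
        n_total = 0
        for _ in range(200):
            fit = fit_node_lmm(_simulate_lmm(rng, beta_group=0.0, n_groups=3))
            contrasts = posthoc_contrasts(fit, force=True)
            n_sig += int((contrasts["p_adjusted"] < 0.05).any())
            n_total += 1
        assert n_sig / n_total <= 0.07


@pytest.fixture(scope="module")
def node_fits():
    config = CohortConfig(
        n_nodes=30,
        groups=(GroupSpec("HC", 10, 2, 0.0), GroupSpec("SP", 10, 2, 0.7)),
        seed=12,
    )
    table = build_metric_table(generate_cohort(config), tau=0.35)
    return fit_all_nodes(table, "degree", weighted=True, reference="HC")


class TestPipelineRecovery:
    """Generate -> threshold -> metrics -> mixed model, end to end."""

    def test_planted_strength_effect_detected(self, node_fits):
        """Severity attenuates strength everywhere; most nodes must flag it."""
        sensitivity = (node_fits["group_omnibus_pvalue"] < 0.05).mean()
        assert sensitivity >= 0.8

    def test_effect_direction_negative(self, node_fits):
        assert (node_fits["effect_SP"] < 0).mean() >= 0.9

    def test_null_pipeline_calibrated(self):
        """Same-severity groups: per-node rejections stay near the nominal rate.

        Within one cohort the node-level tests share the subject draw, so the
        rate is averaged over independent cohorts.
        """
        rates = []
        for seed in (13, 14, 15):
            config = CohortConfig(
                n_nodes=40,
                groups=(GroupSpec("A", 15, 3, 0.3), GroupSpec("B", 15, 3, 0.3)),
                seed=seed,
            )
            table = build_metric_table(generate_cohort(config), tau=0.35)
            fits = fit_all_nodes(table, "degree", weighted=True, reference="A")
            rates.append((fits["group_omnibus_pvalue"] < 0.05).mean())
        assert np.mean(rates) <= 0.12


def test_mixed_model_matches_lme4_reference():
    """Fixed effects agree with an independent lme4 (R) fit of the same model."""
    import subprocess

    rng = np.random.default_rng(1)
    df = _simulate_lmm(rng, n_subjects=30, beta_group=1.5, beta_session=0.2)
    import tempfile, os

    with tempfile.TemporaryDirectory() as d:
        csv = os.path.join(d, "data.csv")
        df.to_csv(csv, index=False)
        script = (
            'suppressMessages(library(lme4)); '
            f'd <- read.csv("{csv}"); '
            'm <- lmer(value ~ group + session + (1|subject_id), data=d, REML=TRUE); '
            'cat(fixef(m), sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", script],
                             capture_output=True, text=True, check=True)
    intercept, group_eff, session_eff = map(float, out.stdout.split())
    fit = fit_node_lmm(df)
    assert fit.intercept == pytest.approx(intercept, abs=1e-4)
    assert fit.group_effects["G1"] == pytest.approx(group_eff, abs=1e-4)
    assert fit.session_effect == pytest.approx(session_eff, abs=1e-4)
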