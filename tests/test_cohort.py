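"""Synthetic cohort generator: design shape, determinism, injected effects."""

import numpy as np
import pandas as pd
import pytest

from iadc.cohort import (
    AgentParams,
    CohortConfig,
    config_from_dict,
    config_to_dict,
    generate_cohort,
    generate_session,
    make_policy,
)
from iadc.tracking import fit_cohort_tracking


def small_config(**kw):
    defaults = dict(n_sessions=6, treatment_split=(3, 3), master_seed=99)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestDesignShape:
    def test_default_cohort_dimensions(self):
        cfg = CohortConfig(n_sessions=4, treatment_split=(2, 2))
        df = generate_cohort(cfg)
        # sessions x 2 blocks x 15 rounds x 6 members
        assert len(df) == 4 * 2 * 15 * 6
        assert set(df.block) == {"sim", "seq"}
        assert df.groupby(["session_id", "block", "round"]).size().eq(6).all()

    def test_single_session_single_round(self):
        cfg = CohortConfig(n_sessions=1, treatment_split=(1, 0), n_rounds=1)
        df = generate_cohort(cfg)
        assert len(df) == 2 * 1 * 6  # two blocks of one round

    def test_counterbalancing_alternates_by_parity(self):
        cfg = small_config()
        even = generate_session(cfg, 0)
        odd = generate_session(cfg, 1)
        first_even = even[even.block_position == 1]["block"].iloc[0]
        first_odd = odd[odd.block_position == 1]["block"].iloc[0]
        assert {first_even, first_odd} == {"sim", "seq"}
        assert first_even == "sim"

    def test_split_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sum to n_sessions"):
            CohortConfig(n_sessions=10, treatment_split=(4, 4))


class TestDeterminism:
    def test_same_config_same_bytes(self):
        cfg = small_config()
        a = generate_session(cfg, 2)
        b = generate_session(cfg, 2)
        pd.testing.assert_frame_equal(a, b)

    def test_sessions_are_distinct(self):
        cfg = small_config()
        a = generate_session(cfg, 0).contribution.to_numpy()
        b = generate_session(cfg, 2).contribution.to_numpy()  # same arm
        assert not np.array_equal(a, b)

    def test_master_seed_changes_output(self):
        a = generate_session(small_config(), 0)
        b = generate_session(small_config(master_seed=100), 0)
        assert not a.contribution.equals(b.contribution)


class TestPolicies:
    def test_full_zero_inflation_contributes_nothing(self):
        p = AgentParams(zero_inflation=1.0, location=10, noise_scale=2)
        pol = make_policy("attacker", p, np.random.default_rng(0))
        assert all(pol(j, [], []) == 0 for j in range(1, 16))

    def test_no_tracking_recovers_location(self):
        p = AgentParams(zero_inflation=0.0, location=8.0, noise_scale=2.0,
                        group_sd=0.0)
        pol = make_policy("attacker", p, np.random.default_rng(1))
        draws = [pol(1, [], []) for _ in range(4000)]
        se = np.std(draws) / np.sqrt(len(draws))
        assert np.mean(draws) == pytest.approx(8.0, abs=4 * se)

    def test_full_anchoring_copies_first_mover(self):
        cfg = small_config()
        for key in cfg.agents:
            cfg.agents[key].anchor_weight = 1.0
        df = generate_session(cfg, 0)
        seq = df[df.block == "seq"]
        var = seq.groupby(["round", "role"])["contribution"].var(ddof=1)
        assert (var == 0).all()

    def test_positive_tracking_weight_rejected(self):
        with pytest.raises(ValueError, match="tracking_weight"):
            AgentParams(0.2, 8, 2, tracking_weight=0.5)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(
        CohortConfig(n_sessions=40, treatment_split=(20, 20), master_seed=7)
    )


class TestInjectedEffects:
    def test_attacker_zero_rate_contrast(self, cohort):
        att = cohort[cohort.role == "attacker"]
        zr = att.groupby("treatment")["contribution"].apply(
            lambda x: (x == 0).mean()
        )
        assert zr[1] > zr[0]

    def test_attacker_variance_contrast(self, cohort):
        sim = cohort[(cohort.block == "sim") & (cohort.role == "attacker")]
        wgv = sim.groupby(["treatment", "session_id", "round"])[
            "contribution"
        ].var(ddof=1).groupby("treatment").mean()
        assert wgv[1] < wgv[0]

    def test_defense_exceeds_attack(self, cohort):
        means = cohort.groupby("role")["contribution"].mean()
        assert means["defender"] > means["attacker"]

    def test_treated_attackers_track_more(self):
        # needs its own cohorts: compare extreme tracking weights
        base = CohortConfig(n_sessions=60, treatment_split=(30, 30),
                            master_seed=5)
        base.agents[("attacker", "placebo")].tracking_weight = 0.0
        base.agents[("attacker", "treated")].tracking_weight = -1.0
        df = generate_cohort(base)
        fits = fit_cohort_tracking(df[df.block == "sim"])
        fits = fits[fits.role == "attacker"]
        arm = fits.session_id.str.slice(1).astype(int) < 30
        placebo_alpha = fits.loc[arm, "alpha_z"].mean()
        treated_alpha = fits.loc[~arm, "alpha_z"].mean()
        assert treated_alpha < placebo_alpha

    def test_sequential_protocol_coordinates_attackers(self, cohort):
        att = cohort[cohort.role == "attacker"]
        wgv = att.groupby(["block", "session_id", "round"])[
            "contribution"
        ].var(ddof=1).groupby("block").mean()
        assert wgv["seq"] < wgv["sim"]

    def test_slow_decision_injection_rate(self, cohort):
        frac = (cohort.decision_time_s > 180).mean()
        assert 0.001 < frac < 0.012  # nominal 0.5%


class TestConfigRoundtrip:
    def test_dict_roundtrip_preserves_generation(self):
        cfg = small_config()
        cfg.agents[("attacker", "treated")].location = 5.5
        cfg2 = config_from_dict(config_to_dict(cfg))
        pd.testing.assert_frame_equal(
            generate_session(cfg, 1), generate_session(cfg2, 1)
        )

    def test_null_config_equalizes_arms(self):
        cfg = small_config().null()
        assert cfg.agents[("attacker", "treated")] == cfg.agents[
            ("attacker", "placebo")
        ]
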