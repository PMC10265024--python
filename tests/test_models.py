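"""Model battery contracts: family dispatch, recovery, interaction dropping."""

import numpy as np
import pandas as pd
import pytest

import callspace as cs
from callspace.models import (
    ModelSpec,
    drop_interaction_if_ns,
    fit_network_model,
    fit_vocal_model,
    network_model_spec,
    vocal_model_spec,
)


def _design(n_flocks=12, blocks=(2, 3, 4, 5)):
    """Balanced study layout: flocks of 4, half young, repeated blocks."""
    rows = []
    for f in range(n_flocks):
        age = "young" if f < n_flocks // 2 else "old"
        for b in range(4):
            for blk in blocks:
                rows.append({
                    "individual": f"F{f}B{b}",
                    "flock": f"F{f}",
                    "age_class": age,
                    "block": blk,
                })
    return pd.DataFrame(rows)


def _gaussian_data(beta_age=0.5, beta_block=0.1, seed=0):
    df = _design()
    rng = np.random.default_rng(seed)
    u_ind = {i: rng.normal(0, 0.3) for i in df["individual"].unique()}
    u_flk = {f: rng.normal(0, 0.2) for f in df["flock"].unique()}
    young = (df["age_class"] == "young").astype(float)
    df["diversity_change"] = (
        beta_age * young
        + beta_block * df["block"]
        + df["individual"].map(u_ind)
        + df["flock"].map(u_flk)
        + rng.normal(0, 0.4, len(df))
    )
    return df


class TestGaussianModel:
    def test_recovers_planted_age_effect(self):
        ests = []
        for seed in range(8):
            fit = fit_vocal_model(
                _gaussian_data(beta_age=0.5, seed=seed),
                vocal_model_spec("diversity_change", interaction=False),
            )
            assert fit.converged
            ests.append(fit.coef("age")["estimate"])
        mean = np.mean(ests)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(mean - 0.5) < 3 * se + 0.05

    def test_reports_t_statistics(self):
        fit = fit_vocal_model(
            _gaussian_data(), vocal_model_spec("diversity_change",
                                               interaction=False)
        )
        assert (fit.table["stat_type"] == "t").all()


class TestNegativeBinomialModel:
    def test_recovers_log_mean_ratio(self):
        ests = []
        for seed in range(8):
            df = _design()
            rng = np.random.default_rng(100 + seed)
            young = (df["age_class"] == "young").to_numpy()
            mu = np.exp(3.0 + 0.3 * young)
            lam = rng.gamma(5.0, mu / 5.0)
            df["vocal_output"] = rng.poisson(lam)
            fit = fit_vocal_model(
                df, vocal_model_spec("vocal_output", interaction=False)
            )
            ests.append(fit.coef("age")["estimate"])
        mean = np.mean(ests)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(mean - 0.3) < 3 * se + 0.03
        fit = fit_vocal_model(
            df, vocal_model_spec("vocal_output", interaction=False)
        )
        assert (fit.table["stat_type"] == "z").all()


class TestBetaModel:
    def test_boundary_values_squeezed_not_fatal(self):
        df = _design(n_flocks=4)
        rng = np.random.default_rng(2)
        df["plasticity"] = rng.beta(5, 2, len(df))
        df.loc[df.index[:3], "plasticity"] = [0.0, 1.0, 1.0]
        fit = fit_vocal_model(
            df, vocal_model_spec("plasticity", interaction=False)
        )
        assert fit.converged
        assert not fit.table.empty

    def test_recovers_logit_age_effect(self):
        ests = []
        for seed in range(8):
            df = _design()
            rng = np.random.default_rng(300 + seed)
            young = (df["age_class"] == "young").to_numpy()
            eta = 0.3 + 0.5 * young
            mu = 1 / (1 + np.exp(-eta))
            phi = 25.0
            df["convergence"] = rng.beta(mu * phi, (1 - mu) * phi)
            fit = fit_vocal_model(
                df, vocal_model_spec("convergence", interaction=False)
            )
            ests.append(fit.coef("age")["estimate"])
        mean = np.mean(ests)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(mean - 0.5) < 3 * se + 0.05


class TestInteractionRule:
    def test_strong_interaction_retained(self):
        df = _gaussian_data(seed=3)
        young = (df["age_class"] == "young").astype(float)
        df["diversity_change"] += 1.0 * young * df["block"]
        fit = drop_interaction_if_ns(df, vocal_model_spec("diversity_change"))
        assert fit.interaction_dropped is False
        assert "age:block" in set(fit.table["term"])

    def test_null_interaction_dropped(self):
        fit = drop_interaction_if_ns(
            _gaussian_data(seed=4), vocal_model_spec("diversity_change")
        )
        assert fit.interaction_dropped is True
        assert "age:block" not in set(fit.table["term"])

    def test_alpha_one_always_reduces(self):
        df = _gaussian_data(seed=5)
        young = (df["age_class"] == "young").astype(float)
        df["diversity_change"] += 2.0 * young * df["block"]
        fit = drop_interaction_if_ns(
            df, vocal_model_spec("diversity_change"), alpha=1.0
        )
        assert fit.interaction_dropped is True


class TestNetworkModels:
    def test_density_separation_detected(self):
        """Strong but incomplete density separation by age yields a positive,
        significant young coefficient."""
        df = pd.DataFrame({
            "flock": [f"F{i}" for i in range(12)],
            "age_class": ["young"] * 6 + ["old"] * 6,
            "density": [1.0, 5 / 6, 1.0, 5 / 6, 1.0, 5 / 6,
                        3 / 6, 4 / 6, 2 / 6, 3 / 6, 4 / 6, 3 / 6],
        })
        fit = fit_network_model(df, network_model_spec("density", "affiliation"))
        age = fit.coef("age")
        assert age["estimate"] > 0
        assert age["p_value"] < 0.05
        assert not fit.degenerate

    def test_complete_separation_flagged_degenerate(self):
        df = pd.DataFrame({
            "flock": [f"F{i}" for i in range(12)],
            "age_class": ["young"] * 6 + ["old"] * 6,
            "density": [1.0] * 6 + [0.0] * 6,
        })
        fit = fit_network_model(df, network_model_spec("density", "agonism"))
        assert fit.degenerate

    def test_gamma_strength_fits_positive_skewed_data(self):
        rng = np.random.default_rng(6)
        rows = []
        for f in range(12):
            age = "young" if f < 6 else "old"
            mu = 1.2 if age == "young" else 0.8
            for b in range(4):
                rows.append({
                    "flock": f"F{f}", "age_class": age,
                    "strength_proximity": rng.gamma(4.0, mu / 4.0),
                })
        fit = fit_network_model(
            pd.DataFrame(rows), network_model_spec("strength", "proximity")
        )
        assert fit.converged
        assert not fit.degenerate


def test_unknown_family_rejected():
    with pytest.raises(ValueError, match="unknown family"):
        ModelSpec(response="x", family="poisson")


def test_nonconvergence_is_flagged_not_raised():
    df = pd.DataFrame({
        "individual": ["a", "b"], "flock": ["f", "f"],
        "age_class": ["young", "old"], "block": [2, 2],
        "vocal_output": [0, 0],
    })
    fit = fit_vocal_model(df, vocal_model_spec("vocal_output",
                                               interaction=False))
    assert isinstance(fit, cs.ModelFit)
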