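import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import smokesim as ss
from smokesim.population import (
    MarginalsError,
    ProfileParseError,
    USES_CC,
    USES_EC,
    generate_population_arrays,
    population_summary,
    profiles_to_frame,
)


def test_degenerate_state_distribution_yields_all_nonusers(simple_marginals):
    simple_marginals.stateProbs = np.array([1.0, 0.0, 0.0, 0.0])
    profiles = ss.generate_profiles(100, simple_marginals, seed=7)
    assert len(profiles) == 100
    assert all(p.state == ss.SmokingState.NONE for p in profiles)
    assert all(p.freqCC == 0.0 and p.freqEC == 0.0 for p in profiles)


def test_seeded_generation_is_reproducible(default_marginals):
    a = profiles_to_frame(ss.generate_profiles(500, default_marginals, seed=1))
    b = profiles_to_frame(ss.generate_profiles(500, default_marginals, seed=1))
    pd.testing.assert_frame_equal(a, b)
    c = profiles_to_frame(ss.generate_profiles(500, default_marginals, seed=2))
    assert not a.equals(c)


def test_state_frequencies_within_exact_binomial_ci(simple_marginals):
    # 99% two-sided binomial interval per category at n = 20000
    n = 20000
    simple_marginals.stateProbs = np.array([0.80, 0.10, 0.05, 0.05])
    arrays = generate_population_arrays(n, simple_marginals, seed=3)
    counts = np.bincount(arrays["state"], minlength=4)
    for k, p in enumerate(simple_marginals.stateProbs):
        lo, hi = binom.interval(0.99, n, p)
        assert lo <= counts[k] <= hi, f"state {k}: {counts[k]} outside [{lo}, {hi}]"


def test_all_discrete_marginals_converge_at_large_n(default_marginals):
    # every discrete category within its 99.9% binomial CI at n = 1e5,
    # with the copula active (it must preserve the marginals)
    n = 100_000
    arrays = generate_population_arrays(n, default_marginals, seed=9)
    checks = [
        (np.bincount(arrays["state"], minlength=4), default_marginals.stateProbs),
        (
            np.bincount(arrays["numSmokingFriends"], minlength=5),
            default_marginals.friendCountProbs,
        ),
        (
            np.bincount((arrays["age"] - 13).astype(int), minlength=7),
            default_marginals.ageProbs,
        ),
    ]
    for counts, probs in checks:
        for k, p in enumerate(probs):
            lo, hi = binom.interval(0.999, n, p)
            assert lo <= counts[k] <= hi


def test_frequency_positive_exactly_when_product_used(default_marginals):
    arrays = generate_population_arrays(20_000, default_marginals, seed=11)
    assert np.array_equal(arrays["freqCC"] > 0, USES_CC[arrays["state"]])
    assert np.array_equal(arrays["freqEC"] > 0, USES_EC[arrays["state"]])


def test_copula_induces_smoker_peer_and_openness_association(default_marginals):
    arrays = generate_population_arrays(50_000, default_marginals, seed=13)
    smoker = USES_CC[arrays["state"]]
    assert arrays["numSmokingFriends"][smoker].mean() > (
        arrays["numSmokingFriends"][~smoker].mean() + 0.3
    )
    assert arrays["baseOpennessCC"][smoker].mean() > (
        arrays["baseOpennessCC"][~smoker].mean() + 0.2
    )


def test_profile_roundtrip_through_csv(tmp_path, simple_marginals):
    profiles = ss.generate_profiles(50, simple_marginals, seed=2)
    path = tmp_path / "profiles.csv"
    ss.write_profiles(profiles, path)
    loaded = ss.load_profiles(path)
    assert loaded == profiles


def test_load_rejects_out_of_range_value_citing_row(tmp_path, simple_marginals):
    profiles = ss.generate_profiles(20, simple_marginals, seed=2)
    df = profiles_to_frame(profiles)
    df.loc[11, "numSmokingFriends"] = 5  # data row 12
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ProfileParseError, match="row 12"):
        ss.load_profiles(path)


def test_load_duplicate_agent_id_rejected(tmp_path, simple_marginals):
    df = profiles_to_frame(ss.generate_profiles(5, simple_marginals, seed=2))
    df.loc[4, "agentId"] = 0
    path = tmp_path / "dup.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ProfileParseError, match="duplicate"):
        ss.load_profiles(path)


def test_load_header_only_file_gives_empty_list(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text(
        "agentId,age,state,numSmokingFriends,baseOpennessCC,"
        "baseOpennessEC,freqCC,freqEC\n"
    )
    assert ss.load_profiles(path) == []


def test_load_missing_column_rejected(tmp_path):
    path = tmp_path / "short.csv"
    path.write_text("agentId,age\n0,15\n")
    with pytest.raises(ProfileParseError, match="freqCC"):
        ss.load_profiles(path)


@pytest.mark.parametrize(
    "field,value",
    [("stateProbs", [0.5, 0.5, 0.1, 0.0]), ("friendCountProbs", [1.0, 0.0, 0.0, -0.1, 0.1])],
)
def test_invalid_probability_vector_names_field(simple_marginals, field, value):
    with pytest.raises(MarginalsError, match=field):
        setattr(simple_marginals, field, np.asarray(value, dtype=float))
        simple_marginals.__post_init__()


def test_nonpositive_n_rejected(simple_marginals):
    with pytest.raises(ValueError):
        ss.generate_profiles(0, simple_marginals, seed=1)


def test_profile_invariants_enforced():
    with pytest.raises(ValueError, match="freqCC"):
        ss.AgentProfile(0, 15, ss.SmokingState.NONE, 0, 0.1, 0.1, 0.5, 0.0)
    with pytest.raises(ValueError, match="numSmokingFriends"):
        ss.AgentProfile(0, 15, ss.SmokingState.NONE, 7, 0.1, 0.1, 0.0, 0.0)


def test_population_summary_reports_marginals(simple_marginals):
    profiles = ss.generate_profiles(200, simple_marginals, seed=4)
    summary = population_summary(profiles)
    assert summary["n"] == 200
    assert abs(sum(summary["stateFractions"].values()) - 1.0) < 1e-9
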