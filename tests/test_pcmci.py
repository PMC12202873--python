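"""Discovery engine: skeleton pruning, orientation rules, MCI control."""
import numpy as np
import pytest

from causalpanel import (
    CausalGraph,
    CausalLink,
    SCMSpec,
    discover_skeleton,
    link_key,
    mci_validate,
    orient_links,
    parcorr_test,
    run_pcmciplus,
    simulate_panel,
)
from conftest import noise_panel


def test_skeleton_false_adjacency_is_bounded_on_independent_noise():
    """Mean false cross-adjacency count stays within the binomial bound."""
    alpha, tau_max, n_seeds = 0.01, 2, 40
    false_total = 0
    for seed in range(n_seeds):
        panel = noise_panel(T=1000, n=3, seed=seed)
        skel = discover_skeleton(panel, tau_max=tau_max, alpha=alpha)
        false_total += sum(
            1 for j in range(3) for (i, tau) in skel.adjacency[j] if i != j
        )
    n_candidates = 3 * 3 * (tau_max + 1) - 3  # ordered, excl. lag-0 self
    assert false_total / n_seeds <= 2 * alpha * n_candidates


def test_planted_lagged_link_is_recovered():
    spec = SCMSpec(n_vars=2, links=((0, 1, 1, 0.5),), auto_coeffs=(0.3, 0.3))
    hits = 0
    n_seeds = 40
    for seed in range(n_seeds):
        panel = simulate_panel(spec, T=2000, seed=seed)
        skel = discover_skeleton(panel, tau_max=3, alpha=0.05)
        hits += (0, 1) in skel.adjacency[1]
    assert hits >= 0.95 * n_seeds


def test_indirect_chain_adjacency_is_conditioned_away():
    """X -> Y -> Z (both lag 1): the lag-2 X-Z adjacency must vanish given Y."""
    spec = SCMSpec(n_vars=3, links=((0, 1, 1, 0.6), (1, 2, 1, 0.6)))
    removed = 0
    n_seeds = 40
    for seed in range(n_seeds):
        panel = simulate_panel(spec, T=2000, seed=100 + seed)
        skel = discover_skeleton(panel, tau_max=3, alpha=0.05)
        removed += (0, 2) not in skel.adjacency[2]
    assert removed >= 0.90 * n_seeds


def test_lagged_links_are_always_directed(mimic_panel):
    graph = run_pcmciplus(mimic_panel, tau_max=7, alpha=0.05)
    assert all(l.orientation == "directed" for l in graph.links if l.lag >= 1)
    assert all(not (l.lag == 0 and l.source == l.sink) for l in graph.links)


def test_contemporaneous_collider_is_oriented_into_the_middle():
    spec = SCMSpec(
        n_vars=3,
        links=((0, 2, 0, 0.5), (1, 2, 0, 0.5)),
        auto_coeffs=(0.3, 0.3, 0.3),
    )
    oriented = 0
    n_seeds = 30
    for seed in range(n_seeds):
        panel = simulate_panel(spec, T=2000, seed=200 + seed)
        graph = run_pcmciplus(panel, tau_max=2, alpha=0.01)
        into_z = {
            (l.source, l.sink)
            for l in graph.links
            if l.lag == 0 and l.orientation == "directed"
        }
        oriented += {(0, 2), (1, 2)} <= into_z
    assert oriented >= 0.90 * n_seeds


def test_isolated_contemporaneous_pair_stays_unoriented():
    spec = SCMSpec(n_vars=2, links=((0, 1, 0, 0.5),), auto_coeffs=(0.3, 0.3))
    panel = simulate_panel(spec, T=2000, seed=3)
    graph = run_pcmciplus(panel, tau_max=2, alpha=0.05)
    lag0 = [l for l in graph.links if l.lag == 0]
    assert len(lag0) == 1
    assert lag0[0].orientation == "unoriented"


def test_mci_reduces_to_plain_parcorr_with_empty_parents():
    panel = noise_panel(T=500, n=2, seed=9)
    graph = CausalGraph(
        n_vars=2,
        tau_max=1,
        alpha=1.0,
        links=[CausalLink(0, 1, 1)],
    )
    validated = mci_validate(panel, graph, alpha=1.0)
    # same alignment as the engine: rows t = 2*tau_max .. T-1
    x = panel.values[1:-1, 0]
    y = panel.values[2:, 1]
    plain = parcorr_test(x, y)
    assert validated.links[0].p_value == pytest.approx(plain.p_value, abs=1e-12)
    assert validated.links[0].rho == pytest.approx(plain.rho, abs=1e-12)


def test_mci_controls_autocorrelation_inflation():
    """Strongly autocorrelated X must not spuriously drive white-noise Y."""
    spec = SCMSpec(n_vars=2, auto_coeffs=(0.9, 0.0))
    tau_max, alpha = 3, 0.05
    false_links = 0
    n_seeds = 60
    for seed in range(n_seeds):
        panel = simulate_panel(spec, T=1000, seed=300 + seed)
        graph = run_pcmciplus(panel, tau_max=tau_max, alpha=alpha)
        false_links += sum(1 for l in graph.links if l.source == 0 and l.sink == 1)
    n_candidates = tau_max + 1  # X -> Y at lags 0..tau_max
    assert false_links / (n_seeds * n_candidates) <= 0.10


def test_strict_alpha_keeps_null_graphs_nearly_empty():
    from causalpanel import make_random_scm

    alpha, tau_max = 0.001, 3
    false_total = 0
    n_seeds = 60
    for seed in range(n_seeds):
        spec = make_random_scm(4, cross_density=0.0, lag_max=1, seed=400 + seed)
        panel = simulate_panel(spec, T=500, seed=500 + seed)
        graph = run_pcmciplus(panel, tau_max=tau_max, alpha=alpha)
        false_total += len(graph.cross_links())
    n_candidates = 6 + 4 * 3 * tau_max  # unordered lag-0 pairs + ordered lagged
    assert false_total / n_seeds <= 2 * alpha * n_candidates


def test_discovery_is_deterministic(mimic_panel):
    a = run_pcmciplus(mimic_panel, tau_max=5, alpha=0.05)
    b = run_pcmciplus(mimic_panel, tau_max=5, alpha=0.05)
    assert a.to_dict() == b.to_dict()


def test_mci_links_nest_across_alpha(mimic_panel):
    graphs = {
        alpha: run_pcmciplus(mimic_panel, tau_max=7, alpha=alpha)
        for alpha in (0.05, 0.01, 0.001)
    }
    keys = {alpha: {link_key(l) for l in g.links} for alpha, g in graphs.items()}
    assert keys[0.001] <= keys[0.01] <= keys[0.05]


def test_too_short_sample_is_rejected():
    panel = noise_panel(T=30, n=4, seed=1)
    with pytest.raises(ValueError, match="too short"):
        discover_skeleton(panel, tau_max=7, alpha=0.05)
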