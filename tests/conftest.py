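"""Shared fixtures and independent brute-force oracles."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from famflux import classify, stats, synth

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# brute-force oracles (plain loops, no shared code with the implementation)

def poisson_pmf_scalar(v: int, m: float) -> float:
    if m <= 0:
        return 1.0 if v == 0 else 0.0
    return math.exp(-m + v * math.log(m) - math.lgamma(v + 1))


def brute_force_family_stats(counts, bins, v_max=450, q_cap=5.0):
    """Recompute w_f, L_f, Q_f from raw counts with plain Python loops."""
    n_b = [len(b.members) for b in bins]
    denom = sum(n * n for n in n_b)
    out = []
    for f in range(counts.shape[0]):
        w_f = 0.0
        l_num = 0.0
        l_den = 0
        per_bin = []
        for b, gb in enumerate(bins):
            vals = [int(counts[f, g]) for g in gb.members]
            n = len(vals)
            nplus = sum(1 for v in vals if v > 0)
            w_fb = n_b[b] * nplus / denom
            w_f += w_fb
            if nplus == 0:
                continue
            mean = sum(vals) / n
            var = sum((v - mean) ** 2 for v in vals) / n
            hist = Counter(v for v in vals if v <= v_max)
            l_fb = 0.5 * sum(
                abs(hist.get(v, 0) / n - poisson_pmf_scalar(v, mean))
                for v in range(v_max + 1)
            )
            l_num += l_fb * nplus
            l_den += nplus
            per_bin.append((w_fb, mean, var))
        qs = [math.log(m / v) for _, m, v in per_bin if v > 0]
        fallback = max(qs) if qs else q_cap
        q_f = sum(
            w_fb * (math.log(m / v) if v > 0 else fallback)
            for w_fb, m, v in per_bin
        )
        l_f = l_num / l_den if l_den else float("nan")
        q_f = q_f if per_bin else float("nan")
        out.append((w_f, l_f, q_f))
    return out


def brute_force_fisher_p(a: int, b: int, c: int, d: int):
    """Exact-rational two-sided Fisher p: sum hypergeometric probabilities of
    all tables with the observed margins no more probable than the observed."""
    from fractions import Fraction

    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    probs = {
        k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


# ---------------------------------------------------------------------------
# the default synthetic study, shared across modules (expensive enough to cache)

@pytest.fixture(scope="session")
def ensemble():
    spec = synth.default_ensemble_spec(seed=7)
    matrix, truth = synth.generate_ensemble(spec)
    transfers = synth.generate_transfer_table(matrix, truth, seed=8)
    annotations = synth.generate_category_annotations(truth, seed=9)
    reference = synth.generate_reference_distances(truth, seed=10)
    return {
        "matrix": matrix,
        "truth": truth,
        "transfers": transfers,
        "annotations": annotations,
        "reference": reference,
    }


@pytest.fixture(scope="session")
def ensemble_stats(ensemble):
    table, per_bin = stats.compute_family_stats(
        ensemble["matrix"], transfers=ensemble["transfers"]
    )
    return table, per_bin


@pytest.fixture(scope="session")
def ensemble_labels(ensemble_stats):
    table, _ = ensemble_stats
    return classify.classify_families(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
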