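"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from silicomap.ssrscan import DEFAULT_MIN_REPEATS, canonical_motif, is_primitive


def brute_force_tracts(seq, min_repeats=None):
    """Enumerate maximal perfect SSR tracts by trying every start and phase.

    Independent of the scanner: for each unit length and start position the
    unit is extended copy by copy; a tract is kept when the unit is
    primitive, the copy count meets the threshold, and no run of the same
    period starts one base earlier (left-maximality over all phases).  The
    same longer-tract-wins overlap rule is applied.  Returns a sorted list
    of (canonical class, repeat count).
    """
    min_repeats = min_repeats or DEFAULT_MIN_REPEATS
    n = len(seq)
    found = []
    for k, thr in min_repeats.items():
        for i in range(n - k + 1):
            unit = seq[i : i + k]
            if any(c not in "ACGT" for c in unit) or not is_primitive(unit):
                continue
            c = 1
            while seq[i + c * k : i + (c + 1) * k] == unit:
                c += 1
            if c < thr:
                continue
            if i >= 1 and seq[i - 1] == seq[i - 1 + k] and seq[i - 1] in "ACGT":
                continue  # same-period run starts earlier: not maximal
            found.append((i, i + c * k, canonical_motif(unit), c))
    found.sort(key=lambda t: (-(t[1] - t[0]), t[0]))
    kept = []
    for t in found:
        if all(t[1] <= u[0] or t[0] >= u[1] for u in kept):
            kept.append(t)
    return sorted((cls, cnt) for (_s, _e, cls, cnt) in kept)


def grid_argmax_r(classes, n_points=2001):
    """Grid-search oracle for the two-point recombination MLE.

    Evaluates the multinomial log-likelihood on an even grid over [0, 0.5]
    and refines the argmax by quadratic interpolation through the three
    surrounding points.  Returns (r, loglik at r).
    """
    from silicomap.linkmap import two_point_loglik

    grid = np.linspace(0.0, 0.5, n_points)
    ll = two_point_loglik(classes, grid)
    k = int(np.argmax(ll))
    if 0 < k < n_points - 1:
        y0, y1, y2 = ll[k - 1], ll[k], ll[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            h = grid[1] - grid[0]
            r = grid[k] + 0.5 * h * (y0 - y2) / denom
        else:
            r = grid[k]
    else:
        r = grid[k]
    r = min(max(float(r), 0.0), 0.5)
    return r, float(two_point_loglik(classes, r))


@pytest.fixture(scope="session")
def small_f2():
    """A 2-chromosome, 200-individual F2 with a known even map (seeded)."""
    from silicomap.simdata import make_truth_map, simulate_f2

    truth_map = make_truth_map(n_groups=2, loci_per_group=15, spacing_cM=10.0)
    gm = simulate_f2(truth_map, 200, seed=11)
    return truth_map, gm
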