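"""Shared fixtures and an exact-arithmetic oracle for the IVW estimators.

The oracle re-evaluates the pooled-estimate, Cochran's Q, I^2, tau^2 and
random-effects formulas in rational arithmetic (fractions.Fraction), fully
independent of the numpy implementation path, so agreement checks are not
self-referential.
"""

from __future__ import annotations

import math
from fractions import Fraction

import pytest

from gwashet import load_fixture


def ivw_oracle(xs, ss):
    """Exact-rational evaluation of the fixed/random IVW quantities.

    Returns a dict with fixed estimate/se/z, q, i2 (percent), tau2, and
    random estimate/se/z.  Square roots are the only floating step.
    """
    x = [Fraction(v) for v in xs]
    s = [Fraction(v) for v in ss]
    k = len(x)
    w = [1 / (si * si) for si in s]
    sw = sum(w)
    xbar = sum(wi * xi for wi, xi in zip(w, x)) / sw
    se_f = math.sqrt(float(1 / sw))
    out = {
        "estimate": float(xbar),
        "se": se_f,
        "z": float(xbar) / se_f,
    }
    if k >= 2:
        q = sum(wi * (xi - xbar) ** 2 for wi, xi in zip(w, x))
        i2 = max(Fraction(0), (q - (k - 1)) / q) * 100 if q > 0 else Fraction(0)
        denom = sw - sum(wi * wi for wi in w) / sw
        tau2 = max(Fraction(0), (q - (k - 1)) / denom) if denom > 0 else Fraction(0)
        wr = [1 / (si * si + tau2) for si in s]
        swr = sum(wr)
        xbar_r = sum(wi * xi for wi, xi in zip(wr, x)) / swr
        se_r = math.sqrt(float(1 / swr))
        out.update(
            q=float(q),
            i2=float(i2),
            tau2=float(tau2),
            estimate_random=float(xbar_r),
            se_random=se_r,
            z_random=float(xbar_r) / se_r,
        )
    return out


@pytest.fixture(scope="session")
def table2_tables():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table3_profiles():
    return load_fixture("table3")


@pytest.fixture(scope="session")
def table3_by_id(table3_profiles):
    return {p.dataset_id: p for p in table3_profiles}
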