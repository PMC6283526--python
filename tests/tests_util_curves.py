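"""Shared curve builders used by acceptance and unit tests."""

import numpy as np

from cetsakit import FoldChangeCurve, LL4Params, ll4_eval

TEMPS = np.arange(37.0, 65.0, 3.0)


def melt_curve(fc, pid="P1", run="r1", treatment="vehicle", rep=1):
    return FoldChangeCurve(
        protein_id=pid, x_values=TEMPS, fold_changes=np.asarray(fc, float),
        x_kind="temperature", run_id=run, treatment=treatment, replicate=rep)


def random_melt_run(n=400, sigma=0.04, seed=2, run="melt1"):
    """Proteins sharing one melting trend plus multiplicative noise."""
    rng = np.random.default_rng(seed)
    base = ll4_eval(LL4Params(b=14.0, c=0.08, d=1.0, e=50.0), TEMPS)
    curves = []
    for i in range(n):
        fc = base / base[0] * np.exp(sigma * rng.standard_normal(10))
        fc[0] = 1.0
        curves.append(melt_curve(fc, pid=f"P{i}", run=run))
    return curves
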