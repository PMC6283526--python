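import numpy as np
import pytest

from cetsakit import ChannelMap, FoldChangeCurve, SimConfig
from cetsakit.synth_data import DEFAULT_DOSE_LADDER, MELT_TEMPERATURES

DOSES = np.array(DEFAULT_DOSE_LADDER)
TEMPS = np.array(MELT_TEMPERATURES, dtype=float)


@pytest.fixture
def itdr_channel_map():
    return ChannelMap(
        run_id="run1", treatment="compound", replicate=1,
        channel_labels=[f"D{i}" for i in range(10)],
        x_values=tuple(DOSES), x_kind="concentration", reference_index=0)


@pytest.fixture
def melt_channel_map():
    return ChannelMap(
        run_id="melt1", treatment="vehicle", replicate=1,
        channel_labels=[f"T{int(t)}" for t in TEMPS],
        x_values=tuple(TEMPS), x_kind="temperature", reference_index=0)


def make_curve(fc, x=None, protein_id="P1", run_id="run1",
               treatment="compound", replicate=1, x_kind="concentration"):
    """Shorthand FoldChangeCurve for crafted examples."""
    if x is None:
        x = DOSES
    return FoldChangeCurve(
        protein_id=protein_id, x_values=np.asarray(x, float),
        fold_changes=np.asarray(fc, float), x_kind=x_kind,
        run_id=run_id, treatment=treatment, replicate=replicate)


@pytest.fixture(scope="session")
def small_itdr_sim():
    """Shared moderate spike-in ITDR simulation (fast, reused read-only)."""
    from cetsakit import simulate_itdr_experiment
    cfg = SimConfig(n_proteins=600, n_binders=30, seed=5, noise_sigma=0.08)
    return simulate_itdr_experiment(cfg)


@pytest.fixture(scope="session")
def small_melt_sim():
    """Shared small duplicate-design melt simulation."""
    from cetsakit import simulate_melt_experiment
    cfg = SimConfig(n_proteins=150, n_binders=8, seed=11, noise_sigma=0.05,
                    max_tm_shift=3.0)
    return simulate_melt_experiment(cfg)
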