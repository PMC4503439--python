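import numpy as np
import pytest

from mangopk.biotransform import ParentSpec, build_rule_table, load_reference_peaklist
from mangopk.records import ConcProfile, DoseEvent
from mangopk.simulate import PKPopulationSpec, simulate_iv_profiles


@pytest.fixture(scope="session")
def rules():
    return build_rule_table()


@pytest.fixture(scope="session")
def parent():
    return ParentSpec(parent_mz=411.21, parent_rt=27.6)


@pytest.fixture(scope="session")
def reference_peaklist():
    """Bundled 16-record metabolite peak list plus its parent spec."""
    return load_reference_peaklist()


@pytest.fixture()
def mono_exp_profile():
    """Exact mono-exponential decay, k = 0.00315/min (t1/2 = 220 min)."""
    t = np.linspace(0.0, 720.0, 13)
    return ConcProfile("s1", t, 2.0 * np.exp(-0.00315 * t), lloq=1e-9)


@pytest.fixture()
def noise_free_1cpt():
    """Noise-free one-compartment IV study calibrated to CL 31.4 / V 4304."""
    sched = tuple(float(x) for x in np.arange(0.0, 2401.0, 5.0))
    spec = PKPopulationSpec(
        cl=31.4, v1=4304.0, q=0.0, omega=0.0, sigma_prop=0.0,
        n_subjects=1, schedule=sched, lloq=1e-9,
    )
    profile = simulate_iv_profiles(spec, 5.0)[0]
    dose = DoseEvent(profile.subject_id, "iv_bolus", 5.0)
    return profile, dose
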