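import numpy as np
import pytest
from hypothesis import settings

import anomer as an

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lactose_model() -> an.SolubilityModel:
    """Default 25 C lactose-water solubility model."""
    return an.SolubilityModel()


@pytest.fixture(scope="session")
def type3_result() -> an.SimResult:
    """Persistent-suspension run: loading above the total saturation
    concentration, integrated past mutarotation equilibration."""
    return an.simulate(an.SimulationParams(loading=0.25, horizon_h=24.0))


@pytest.fixture(scope="session")
def type2_result() -> an.SimResult:
    """Full-dissolution-after-mutarotation run: loading between the alpha
    and total saturation concentrations."""
    return an.simulate(an.SimulationParams(loading=0.15, horizon_h=15.0))


def conservation_errors(result: an.SimResult, times_h) -> dict[str, float]:
    """Max relative drift of the three conserved totals along a run."""
    p = result.params
    chi = p.chi
    m_w0 = p.water_mass_g * 1e-3
    m_susp = m_w0 * (1.0 + p.loading)
    times_h = np.asarray(times_h, dtype=float)
    raw = result._sampler(times_h, raw=True)
    ell, m_a, m_b, m_w = raw
    rem = np.maximum(result.seed_sizes[:, None] - ell[None, :], 0.0)
    m_cry = (
        p.rho_c * p.k_v * np.sum(result._seed_weights[:, None] * rem**3, axis=0) * m_susp
        if result.seed_sizes.size
        else np.zeros_like(ell)
    )
    lactose = m_a + m_b + chi * m_cry
    water = m_w + (1.0 - chi) * m_cry
    total = m_a + m_b + m_w + m_cry
    return {
        name: float(np.max(np.abs(series - series[0])) / series[0])
        for name, series in (("lactose", lactose), ("water", water), ("total", total))
    }
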