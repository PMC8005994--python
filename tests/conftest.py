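import numpy as np
import pytest

from masscap import BatchRecord, CapsuleObservation, FormulationSpec, SimulatorParams

# Published density characterization of the three bulking agents
# (mean over n = 3 replicates): agent -> (rho_b, rho_c) in g/mL.
AGENT_DENSITIES = {
    "m35": (0.531, 0.705),
    "la": (0.564, 0.781),
    "mcc": (0.392, 0.443),
}


@pytest.fixture
def baclofen_1mg_spec() -> FormulationSpec:
    return FormulationSpec(
        dose=1.0, n_capsules=30, overage_fraction=0.10,
        capsule_volume=0.5, glidant_fraction=0.005,
        api_name="baclofen", agent="m35",
    )


@pytest.fixture
def default_params(baclofen_1mg_spec) -> SimulatorParams:
    rho_b, rho_c = AGENT_DENSITIES["m35"]
    return SimulatorParams(
        spec=baclofen_1mg_spec,
        bulk_density=rho_b,
        compressed_density=rho_c,
        seed=1234,
        batch_id="m35-1mg-sim",
    )


def make_batch(
    contents,
    gross=None,
    label_claim=1.0,
    tare=74.0,
    weighed_blend=None,
    batch_id="test",
):
    """Hand-built BatchRecord for unit tests."""
    contents = np.asarray(contents, dtype=float)
    if gross is None:
        gross = np.full(contents.size, 290.0)
    gross = np.asarray(gross, dtype=float)
    capsules = tuple(
        CapsuleObservation(index=i + 1, gross_mass=g, content=c)
        for i, (g, c) in enumerate(zip(gross, contents))
    )
    net = float(gross.sum()) - tare * contents.size
    return BatchRecord(
        batch_id=batch_id,
        label_claim=label_claim,
        capsules=capsules,
        weighed_api=float(contents.sum()),
        weighed_blend=weighed_blend if weighed_blend is not None else net,
        shell_tare_mean=tare,
    )
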