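#!/usr/bin/env python
"""Blend compositions for the full dose x agent grid.

Recomputes the required bulking-agent mass from the published densities and
derives every blend (API with 10 % overage, filler, glidant) for 30-capsule
batches of baclofen (1, 2.5, 4 mg) and spironolactone (0.5, 2, 4 mg).
Writes results/blend_compositions.csv.
"""

from pathlib import Path

import pandas as pd

from masscap import FormulationSpec, blend_composition, required_bulking_mass
from masscap import io as mio

RESULTS = Path(__file__).resolve().parents[1] / "results"
DOSES = {"baclofen": [1.0, 2.5, 4.0], "spironolactone": [0.5, 2.0, 4.0]}


def main():
    dens = mio.load_published_densities().set_index("agent")
    rows = []
    for agent in dens.index:
        m_b = required_bulking_mass(
            dens.loc[agent, "bulk_density_g_ml"],
            dens.loc[agent, "compressed_density_g_ml"], 0.5, 30,
        )
        for api, doses in DOSES.items():
            for dose in doses:
                spec = FormulationSpec(
                    dose=dose, n_capsules=30, api_name=api, agent=agent
                )
                c = blend_composition(spec, m_b).rounded()
                rows.append(
                    {
                        "api": api, "dose_mg": dose, "agent": agent,
                        "bulking_mass_g": round(m_b, 3),
                        "api_mass_mg": c.api_mass,
                        "filler_mass_mg": c.filler_mass,
                        "glidant_mass_mg": c.glidant_mass,
                        "target_fill_mass_mg": c.target_fill_mass,
                    }
                )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "blend_compositions.csv", index=False)
    print(df.to_string(index=False))
    print(f"\nwrote {RESULTS / 'blend_compositions.csv'}")


if __name__ == "__main__":
    main()
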