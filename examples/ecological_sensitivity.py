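"""How birth and death rates shape wild-type recovery after a failed drive.

At a drive-failing cost (s = 0.30) the wild type recovers; how fast
depends on the ecology. Under density-dependent births, doubling the
death rate (mu: 0.1 -> 0.2) roughly halves the recovery time, while
doubling the birth rate barely matters. The density parameter a is
re-solved per scenario so the equilibrium stays at 10,000.
"""

import numpy as np

import underdrive as ud
from underdrive.experiments import DEFAULT_SCENARIOS, sensitivity_scenarios
from underdrive.density import Family, Mode

configs = [(Family.MSS, Mode.BIRTHS, 0.5), (Family.BELLOWS, Mode.BIRTHS, 2.0)]
df = sensitivity_scenarios(
    np.array([0.30]),
    configs=configs,
    scenarios=DEFAULT_SCENARIOS,
    protocol=ud.SimulationProtocol(horizon=100),
)

table = df.pivot_table(index=["family", "b"], columns="scenario", values="return_generations")
print(table[["control", "high_r", "high_mu"]].to_string())
print(
    "\nReturn times are in generations after release. high_mu (mu = 0.2)"
    "\nroughly halves the control values; high_r (r = 2.1) changes little"
    "\nunder density-dependent births."
)
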