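#!/usr/bin/env python
"""Calibrate the drug kill thresholds on the scaled vascular fixture.

Procedure (run once; the resulting values are frozen as the defaults
``drug_theta_quiescent`` / ``drug_theta_necrotic`` in SimulationParams):

1. run the reference chemotherapy schedule (3 cycles of 5 days starting day
   3, scaled clock) at 5 ug/m^2 with the kill rule disabled, so cells record
   their cumulative drug uptake undisturbed;
2. theta_1 (mitotic arrest) = the 90th percentile of the per-cell
   cumulative uptake under the low dose, rounded;
3. theta_2 (direct necrosis) = 2.5 x theta_1, rounded.

Placing theta_1 at the top decile of the low-dose exposure makes 5 ug/m^2
arrest only the most exposed cells (treatment failure: the tumor regrows),
while the roughly two-fold higher exposure at 10 ug/m^2 pushes most of the
population over the threshold and the arrest->death cascade clears the
tumor, reproducing the intended dose-response separation.

Usage:  python scripts/calibrate_kill_thresholds.py [--seed 3]
"""

from __future__ import annotations

import argparse

import numpy as np

from tumorcpm import lattice as lat
from tumorcpm import make_fixture, run_simulation
from tumorcpm.simulate import SimulationParams
from tumorcpm.therapy import TherapyProtocol


def exposure_quantile(dose: float, seed: int, q: float = 90.0) -> float:
    params = SimulationParams(minutes_per_mcs=60.0,
                              drug_theta_quiescent=np.inf,
                              drug_theta_necrotic=np.inf)
    protocol = TherapyProtocol(kind="chemo", dose=dose, cycle_days=5.0,
                               n_cycles=3, start_day=3.0)
    state = {}
    run_simulation(make_fixture("vascular28", seed=seed), protocol,
                   days=20.0, seed=seed, params=params,
                   on_day=lambda d, L, f: state.update(L=L))
    cums = [r.cum_drug for r in state["L"].cells.values()
            if r.type in (lat.TP, lat.TM, lat.TQ)]
    return float(np.percentile(cums, q))


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=3)
    args = parser.parse_args()

    lo = exposure_quantile(5.0, args.seed, q=90.0)
    theta1 = round(lo)
    theta2 = round(2.5 * theta1)
    print(f"p90 cumulative uptake, dose 5 ug/m^2: {lo:.2f}")
    print(f"theta_1 (arrest)   = {theta1}")
    print(f"theta_2 (necrosis) = {theta2}")


if __name__ == "__main__":
    main()
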