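"""From encounter rates to kill rates: the Holling disc equation.

Feeds the interaction encounter-rate law E = A N^b + beta1 N^b S (with the
reference coefficients A = 7.43e-2, b = 1.15, beta1 = 2.74e-3) through
f = E / (1 + E T_h) and prints the kill-rate ratio between landscapes with
and without seismic lines for small- and large-bodied prey.
"""
import numpy as np
import pandas as pd

from linefpt import fit_candidate, response_curve, response_ratio
from linefpt.funcresp import HANDLING_LARGE_H, HANDLING_SMALL_H

# embed the reference law in a CandidateFit by fitting exact data
N = np.tile(np.linspace(0.1, 3.0, 20), 3)
S = np.repeat([0.0, 4.46, 8.91], 20)
E = 7.43e-2 * N**1.15 + 2.74e-3 * N**1.15 * S
c3 = fit_candidate("C3", pd.DataFrame({"N": N, "S": S, "E": E}))
print({k: round(v, 5) for k, v in c3.params.items()})

grid = np.array([0.16, 0.5, 1.0, 2.0, 3.0])
for T_h, body in ((HANDLING_SMALL_H, "small-bodied"), (HANDLING_LARGE_H, "large-bodied")):
    for S_val in (4.46, 8.91):
        r = response_ratio(
            response_curve(c3, S_val, T_h, N_grid=grid),
            response_curve(c3, 0.0, T_h, N_grid=grid),
        )
        vals = ", ".join(f"{v:.3f}" for v in r["ratio"])
        print(f"T_h = {T_h:4.1f} h ({body}), S = {S_val}: ratio(N) = [{vals}]")
print("ratios exceed 1 everywhere, are largest at low prey density, and are")
print("larger for the shorter handling time: lines raise kill rates most for")
print("scarce, quickly-handled prey.")
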