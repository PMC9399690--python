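"""Antigen dose response of first- vs second-generation CAR constructs.

Simulates single cells across a log-spaced antigen grid and prints the
steady ppERK fraction and activation time per dose. The CD28-bearing
construct activates at lower antigen density (left-shifted dose curve)
and reaches threshold faster at every dose.
"""

import numpy as np

from cartsim import GEN1, GEN2, assemble_model, default_registry, dose_response

registry = default_registry()
grid = np.geomspace(0.3, 45.0, 10)

for label, construct in (("generation 1 (CD3z only)", GEN1),
                         ("generation 2 (CD3z + CD28)", GEN2)):
    net = assemble_model(construct, registry)
    curve = dose_response(net, grid)
    print(f"\n{label}")
    print(f"{'antigen':>10} {'steady ppERK':>13} {'T_ERK (min)':>12}")
    for _, row in curve.iterrows():
        t = f"{row.activation_time:10.2f}" if row.active else "  censored"
        print(f"{row.antigen:10.2f} {row.final_pperk_fraction:13.3f} {t:>12}")
    thr = curve[curve.active]["antigen"].min()
    print(f"-> lowest activating antigen on this grid: {thr:.2f} molecules/um^2")
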