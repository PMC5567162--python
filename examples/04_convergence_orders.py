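"""Mean-square convergence orders of the integrators.

With additive noise both splitting schemes converge with mean-square order
one; without noise the symmetric Strang composition is second order while the
Lie-Trotter compositions stay first order.
"""

from jrnmm import estimate_ms_order, get_preset

preset = get_preset("alpha_C135")
params, inputs = preset.params(), preset.inputs()

for scheme in ("ou", "wiener"):
    rep = estimate_ms_order(scheme, params, inputs, T=1.0,
                            dt_list=[4e-3, 2e-3, 1e-3, 5e-4], n_paths=500, seed=1)
    print(f"{scheme:7s} splitting, noisy regime:  order {rep.slope:.2f} +- {rep.slope_se:.2f}")

quiet = inputs.with_sigma(0.0)
for scheme, label in (("strang", "Strang"), ("wiener", "Lie-Trotter")):
    rep = estimate_ms_order(scheme, params, quiet, T=1.0,
                            dt_list=[2e-3, 1e-3, 5e-4, 2.5e-4], n_paths=1, seed=1)
    print(f"{label:12s} deterministic:     order {rep.slope:.2f}")
print("-> order one with noise; the Strang composition gains an order when the noise is off")
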