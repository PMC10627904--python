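"""BIC-guided search for the sparse temporal network.

Simulates from the published 20-edge network, runs the prune/expand
search from the full model, and compares the recovered edge set with the
generating one.  At this sample size the strong edges are recovered
reliably; edges near |beta| = 0.03 sit at the detection boundary.
"""

import numpy as np

from panelnet import make_default_scenario, search_model, simulate_panel, reference_network

ds = simulate_panel(make_default_scenario(n_subjects=4000, seed=1))
res = search_model(ds)

true = reference_network() != 0
found = res.fit.mask.free_B
tp = int((true & found).sum())
fp = int((~true & found).sum())
fn = int((true & ~found).sum())
print(f"search finished after {res.n_sweeps} sweep(s)")
print(f"retained edges : {int(found.sum())} (generating model has {int(true.sum())})")
print(f"true/false positives: {tp}/{fp}, missed: {fn}")
print(f"edge-set F1    : {2 * tp / (2 * tp + fp + fn):.3f}")
print(f"BIC start -> final : {res.trace[0]['bic']:.1f} -> {res.fit.bic:.1f}")
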