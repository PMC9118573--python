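"""Extract structural parameters from a Langmuir compression isotherm.

Generates a synthetic di-16:0 phosphatidylcholine-like curve (with an LE/LC
plateau) plus mild pressure noise, runs the feature pipeline and compares
with the generator's ground truth.
"""

from monofilm import extract_features
from monofilm.synthetic import generate_isotherm, isotherm_preset

spec = isotherm_preset("pc160_20C", sigma_pi=0.1, seed=42)
iso, truth = generate_isotherm(spec)
feats = extract_features(iso)
tv = truth.values

print(f"{'parameter':<12}{'extracted':>12}{'truth':>10}")
print(f"{'A_lim':<12}{feats.a_lim:>12.2f}{tv['A_lim_true']:>10.2f}   Angstrom^2")
print(f"{'pi_coll':<12}{feats.pi_coll:>12.2f}{tv['pi_coll_true']:>10.2f}   mN/m")
print(f"{'pi_plateau':<12}{feats.pi_plateau:>12.2f}{tv['pi_plateau_true']:>10.2f}   mN/m")
print(f"{'Cs^-1_max':<12}{feats.cs_inv_max:>12.1f}{tv['cs_inv_max_true']:>10.1f}   mN/m")
print()
print(
    "A_lim is the area of a maximally packed molecule (condensed-branch\n"
    "tangent at pi = 0); pi_coll the pressure where the film fails;\n"
    "pi_plateau the LE/LC coexistence pressure; Cs^-1_max the film's\n"
    "maximal in-plane stiffness."
)
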