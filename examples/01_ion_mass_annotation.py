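"""Annotate observed negative-mode ions with candidate molecular formulas.

Computes [M-H]- m/z values for a small panel of plant antioxidants and
matches a measured ion against them with signed mDa errors.
"""

from scamp import deprotonated_mz, match_formula, parse_formula, render_formula

PANEL = {
    "gallic acid": "C7H6O5",
    "quercetin": "C15H10O7",
    "chlorogenic acid": "C16H18O9",
    "rutin": "C27H30O16",
}

print("calculated [M-H]- m/z:")
formulas = {}
for name, text in PANEL.items():
    f = parse_formula(text)
    formulas[name] = f
    print(f"  {name:18s} {render_formula(f):10s} {deprotonated_mz(f):.5f}")

observed = 169.01426  # a measured ion from a fraction spectrum
print(f"\nmatching observed ion {observed}:")
for f, err_mda, within in match_formula(observed, list(formulas.values()), tol=1.0):
    flag = "MATCH" if within else "     "
    print(f"  {flag} {render_formula(f):10s} error {err_mda:+8.2f} mDa")
# The sub-0.1 mDa match identifies the ion as deprotonated gallic acid;
# every other candidate is tens of mDa away, far outside FT-ICR accuracy.
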