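"""Repeated-measures power planning for a four-condition within design.

Computes the noncentral-F power of the one-way repeated-measures test at a
medium effect size (Cohen's f = 0.25) with assumed correlation rho = 0.5
among the repeated measures, and solves for the smallest sample size
reaching 80% power.
"""

from pupilpipe.stats import required_n, rm_power

n, m, f = 24, 4, 0.25
power = rm_power(n=n, m=m, f=f, alpha=0.05, rho=0.5, epsilon=1.0)
print(f"power at n={n}, m={m} levels, f={f}, alpha=0.05, rho=0.5: {power:.4f}")

n_req = required_n(m=m, f=f, target_power=0.80, alpha=0.05, rho=0.5)
print(f"smallest n reaching 80% power: {n_req}")

print("\nsensitivity (power by sample size):")
for n_i in (12, 16, 20, 24, 28, 32):
    print(f"  n = {n_i:2d}: power = {rm_power(n_i, m, f):.3f}")
print("note: lower assumed correlation or nonsphericity (epsilon < 1) "
      "reduces power; both are arguments of rm_power.")
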