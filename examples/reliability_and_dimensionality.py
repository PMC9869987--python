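"""Internal consistency of short and full determinant measures.

Simulates a one-factor 'full' four-item attitude measure and its
two-item short form, then reports the eigenvalue screen, McDonald's
omega (with a bootstrap CI) for the full version, and the
Spearman-Brown coefficient for the short version.
"""

import numpy as np

from ciberlite import eigen_screen, mcdonald_omega, spearman_brown

rng = np.random.default_rng(1)
n, loading = 400, 0.75
factor = rng.standard_normal(n)
full = loading * factor[:, None] + np.sqrt(1 - loading**2) * rng.standard_normal((n, 4))
short = full[:, :2]  # the two items kept in the short form

screen = eigen_screen(full)
print("eigenvalues:", [round(v, 2) for v in screen.eigenvalues])
print("factors with eigenvalue > 1:", screen.n_factors_kaiser)

omega = mcdonald_omega(full, level=0.95, bootstrap_reps=500, seed=7)
print(
    f"omega (full, 4 items) = {omega.estimate:.3f} "
    f"[{omega.ci.lower:.3f}; {omega.ci.upper:.3f}]  ({omega.extraction} fit)"
)

sb = spearman_brown(short[:, 0], short[:, 1])
print(f"Spearman-Brown (short, 2 items) = {sb.estimate:.3f}")
print("A one-factor screen plus high omega/rho supports scoring each as one composite.")
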