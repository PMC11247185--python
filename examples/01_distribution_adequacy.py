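"""Which count model fits snRNA-seq-like UMI data?

Simulates an NB count matrix (the regime real pseudonegative controls
live in), fits all four candidate models sharing the mean structure
mu_cg = s_c * pi_g, and ranks them by BIC. The recovered global
dispersion should sit near the simulation truth phi = 1, and nb_global
should win the BIC comparison while the gene-wise NB pays for its 2G
parameters.
"""

import warnings

from nucdist import SimCountConfig, bic_compare, fit_model, simulate_counts

warnings.filterwarnings("ignore", category=RuntimeWarning)

m, truth = simulate_counts(
    SimCountConfig(n_genes=300, n_cells=600, model="nb", phi=1.0, seed=0)
)
print(f"matrix: {m.n_genes} genes x {m.n_cells} cells, "
      f"median library size {int(sorted(m.library_sizes)[m.n_cells // 2])} UMIs")

fits = [fit_model(m, name)
        for name in ("binomial", "poisson", "nb_global", "nb_genewise")]
nb = next(f for f in fits if f.model == "nb_global")
print(f"\ntrue dispersion phi = 1.0, fitted phi = {nb.phi_global:.3f}")

print("\nBIC ranking (best first; delta to best):")
print(bic_compare(fits).to_string(index=False, float_format="%.1f"))
print("\nnb_global wins: one extra parameter buys the overdispersion the "
      "equidispersed models cannot express, while the gene-wise NB's 2G "
      "parameters cost more BIC penalty than they earn in likelihood.")
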