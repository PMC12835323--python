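"""Compare the burst-suppression modelling strategies on one cohort.

Fits the POD logistic model with each BS representation (binary any-BS,
raw duration in seconds, continuous BSR) plus the two agent subgroups and
the BS-only dose-response model, and prints the BS term of each.
"""

import bsdetect as bd

cohort = bd.generate_cohort(bd.CohortSimSpec(n=50_000, seed=4))

fits = {
    "binary any-BS": bd.fit_pod_model(cohort, bs_mode="binary"),
    "raw duration (s)": bd.fit_pod_model(cohort, bs_mode="raw_duration"),
    "continuous BSR (%)": bd.fit_pod_model(cohort, bs_mode="continuous_bsr"),
    "sevoflurane subgroup": bd.fit_pod_model(cohort, bs_mode="binary", subset="sevoflurane"),
    "propofol subgroup": bd.fit_pod_model(cohort, bs_mode="binary", subset="propofol"),
    "BS-only dose-response": bd.fit_pod_model(cohort, bs_mode="raw_duration", subset="bs_only"),
}

print(f"{'model':24s} {'BS term':>20s} {'OR':>8s} {'95% CI':>18s} {'p':>10s}")
for name, res in fits.items():
    term = next(t for t in res.table.index if "bs" in t or "dur" in t.lower())
    row = res.table.loc[term]
    ci = f"[{row['ci_low']:.3f}, {row['ci_high']:.3f}]"
    print(f"{name:24s} {term:>20s} {row['or']:8.3f} {ci:>18s} {row['p']:10.2e}")

# The binary indicator mixes the two conditional effects (1.50 under
# propofol, 5.70 under sevoflurane); the subgroup fits isolate each.
# Duration/BSR terms are per-unit ORs and sit close to 1 because the
# effect in the generator acts through BS presence, not its length.
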