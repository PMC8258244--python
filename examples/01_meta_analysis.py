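"""Pool per-disease MR odds ratios across Th1-mediated autoimmune diseases.

A fixed-effect inverse-variance meta-analysis needs only each disease's
odds ratio and 95% CI: the log-scale SE is recovered from the CI width.
Here we pool published-style IVW rows for inflammatory bowel disease,
rheumatoid arthritis and multiple sclerosis (all per unit of genetically
predicted alcohol consumption), once with all instruments and once with
the confounder-curated instrument sets.
"""

from summr import MetaInput, meta_fixed

all_instruments = {
    "IBD": (0.84, 0.54, 1.29),
    "RA": (0.80, 0.54, 1.19),
    "MS": (0.75, 0.49, 1.12),
}
curated_instruments = {
    "IBD": (0.78, 0.44, 1.36),
    "RA": (0.51, 0.30, 0.88),
    "MS": (0.85, 0.50, 1.42),
}

for label, rows in (("all instruments", all_instruments),
                    ("confounder-curated instruments", curated_instruments)):
    res = meta_fixed([MetaInput.from_or_ci(k, *v) for k, v in rows.items()])
    lo, hi = res.or_ci
    print(f"Th1 meta ({label}): OR = {res.odds_ratio:.2f} "
          f"({lo:.2f}-{hi:.2f}), p = {res.pvalue:.2f}")

print()
print("An OR below 1 means genetically higher alcohol consumption associates")
print("with lower pooled disease risk; the curated analysis is nominally")
print("significant (p < 0.05) but would not survive a 0.05/4 correction.")
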