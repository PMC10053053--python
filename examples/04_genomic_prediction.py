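"""Predict purebred candidates' breeding values from crossbred phenotypes
with GBLUP and the sparse Bayesian mixture model.

Accuracy is the Pearson correlation between GEBV and true breeding value
over the candidate set; Best10%_TBV (mean TBV of the top decile by GEBV)
proxies the response to selection.
"""

from dataclasses import replace

from crossgp.experiment import desk_preset, run_experiment

cfg = desk_preset(seed=0)
cfg = replace(cfg, h2_levels=(0.1,), schemes=("PB", "CB_random", "CB_extreme"),
              sizes=(1000,), models=("GBLUP",), replicates=3)
res = run_experiment(cfg)

print("desk-scale system:", res.counts())
print("\nper-scheme averages over 3 replicates (h2 = 0.1, n = 1000, GBLUP):")
cols = ["scheme", "accuracy", "best10_tbv", "accuracy_Duroc",
        "accuracy_Landrace", "accuracy_Yorkshire"]
print(res.averages[cols].round(3).to_string(index=False))
print("\nExtreme-phenotype crossbred genotyping typically predicts the "
      "purebred candidates better than random crossbred genotyping at low "
      "heritability, and is strongest for the terminal sire breed (Duroc), "
      "which contributes half of every commercial animal's genome.")
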