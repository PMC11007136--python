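"""Recover confusion matrices from a published accuracy table.

Diagnostic-accuracy tables usually print sensitivity/specificity/PPV/NPV
as rounded percentages without the underlying counts. With the total
number of decisions known (here 45 = 9 specimens x 5 margin regions), an
exhaustive search over integer confusion matrices often pins down the
counts uniquely — after which the exact Clopper-Pearson intervals can be
recomputed and checked against the printed ones.
"""

import digispec as ds

published = {
    "radiologist 1 (histology 3D reference)": (94, 61, 59, 94),
    "radiologist 2 (histology 3D reference)": (88, 71, 65, 91),
}

for label, metrics in published.items():
    matrices = ds.reconstruct_confusion_matrices(metrics, n=45)
    print(f"{label}: printed sens/spec/PPV/NPV = "
          + "/".join(f"{m}%" for m in metrics))
    print(f"  {len(matrices)} matching matrix(es): {matrices}")
    for tp, fn, fp, tn in matrices:
        rep = ds.accuracy_from_counts(tp, fn, fp, tn)
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            est = getattr(rep, name)
            lo, hi = est.ci95_percent
            print(f"    {name:<12} {est.percent:>3}%  (95% CI {lo}% - {hi}%)"
                  f"   [{est.successes}/{est.trials}]")
print("A unique reconstruction means the printed rounded percentages admit")
print("exactly one underlying confusion matrix at this sample size.")
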