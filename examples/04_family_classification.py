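"""Cross-validated family classification on motif-defined families.

Runs the full benchmark protocol: generate 5 synthetic families (each
defined by three 9-residue motifs, 10% per-position mutation) plus a
random background, train the 100-dimensional embedding on all sequences,
embed every sequence as its summed 3-gram vector, and cross-validate one
balanced family-vs-background SVM task per family.
"""

from protembed import protocols

bench = protocols.family_benchmark(seed=7, folds=10)
print("task            n    sens   spec   acc")
for r in bench["results"]:
    print(f"{r.task_name:<12} {r.n_instances:4d}  "
          f"{r.sensitivity:.3f}  {r.specificity:.3f}  {r.accuracy:.3f}")
print(f"\nweighted averages over {bench['n_instances']} instances: "
      f"sensitivity {bench['weighted_sensitivity']:.3f}, "
      f"specificity {bench['weighted_specificity']:.3f}, "
      f"accuracy {bench['weighted_accuracy']:.3f}")
print("high accuracy reflects the planted motif signal surviving both "
      "mutation and the summation into one 100-dimensional vector.")
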