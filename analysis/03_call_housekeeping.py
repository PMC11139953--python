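"""Call housekeeping genes on both Gini axes and evaluate recovery.

At the default threshold (Gini < 0.2) the subject axis calls the genes
stable across all pooled samples, the tissue axis those below threshold
in every tissue, and their intersection is the combined list.

Found: the intersection recovers the planted stable class with precision
and recall above 0.9.  The tissue axis also admits the planted
tissue-variable and tissue-specific classes — genes tight within each
tissue yet very unequal between tissues — which is exactly why the
subject axis is needed; none of those classes survives the intersection.
Called lists grow monotonically with the threshold.

Writes results/recovery_summary.tsv, results/recovery_confusion.tsv and
results/threshold_sweep.tsv.
"""

import os

import pandas as pd

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))

from hkgini.annotation import split_by_biotype
from hkgini.pipeline import build_score_table, call_housekeeping, filter_expressed
from hkgini.simulate import SimConfig, evaluate_recovery, generate_cohort


def main(seed: int = 1) -> None:
    cohort, catalog, truth = generate_cohort(SimConfig(seed=seed))
    coding, _ = split_by_biotype(catalog)
    kept, _ = filter_expressed(cohort, coding, 0.05)
    scores = build_score_table(cohort, kept)

    call = call_housekeeping(scores, gini_threshold=0.2, mode="lt")
    report = evaluate_recovery(call, truth)
    print(f"subject axis {len(call.subject_axis)}, tissue axis "
          f"{len(call.tissue_axis)}, intersection {len(call.intersection)}")
    print(report)
    print("\nper-class membership of each list:")
    print(report.confusion.to_string())

    os.makedirs(os.path.join(ROOT, "results"), exist_ok=True)
    report.summary.to_csv(os.path.join(ROOT, "results", "recovery_summary.tsv"),
                          sep="\t", float_format="%.4g", index_label="list")
    report.confusion.to_csv(
        os.path.join(ROOT, "results", "recovery_confusion.tsv"),
        sep="\t", index_label="gene_class",
    )

    rows = []
    for thr in (0.05, 0.1, 0.15, 0.2, 0.3, 0.5):
        c = call_housekeeping(scores, gini_threshold=thr)
        r = evaluate_recovery(c, truth).summary.loc["intersection"]
        rows.append({"threshold": thr,
                     "n_subject": len(c.subject_axis),
                     "n_tissue": len(c.tissue_axis),
                     "n_intersection": len(c.intersection),
                     "intersection_precision": r["precision"],
                     "intersection_recall": r["recall"]})
    sweep = pd.DataFrame(rows)
    sweep.to_csv(os.path.join(ROOT, "results", "threshold_sweep.tsv"),
                 sep="\t", index=False, float_format="%.4g")
    print("\nthreshold sweep:")
    print(sweep.to_string(index=False))


if __name__ == "__main__":
    main()
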