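"""Partition per-transcript variance and contrast parents against RILs.

Fits abundance ~ replicate + genotype + treatment + genotype:treatment per
transcript (type III SS, sum-to-zero contrasts) separately for the two
parental lines and the RIL set, clusters the RIL variance profiles with
k-means (k = 10), and reports the mean proportion per term. The expected
signature: parental variance is dominated by treatment, RIL variance
shifts into genotype and genotype x treatment.
"""
from pathlib import Path

from plastiqtl.core_io import read_expression, write_table
from plastiqtl.variance import (cluster_variance_profiles, decompose_variance,
                                summarize_variance)

SEED = 20260928
BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = read_expression(BASE / "data" / "expression.tsv",
                         BASE / "data" / "samples.tsv")
    out = BASE / "variance"
    out.mkdir(parents=True, exist_ok=True)
    groups = {
        "parents": ds.subset_genotypes(["Bay", "Sha"]),
        "rils": ds.subset_genotypes(
            [g for g in ds.genotypes if g not in ("Bay", "Sha")]),
    }
    for name, sub in groups.items():
        decomp = decompose_variance(sub)
        table = decomp.table.copy()
        if name == "rils":
            labels, centroids = cluster_variance_profiles(decomp, k=10,
                                                          seed=SEED)
            table["cluster"] = labels.reindex(table.index).astype("Int64")
            write_table(centroids, out / "cluster_centroids.tsv",
                        index_label="cluster")
        write_table(table, out / f"variance_{name}.tsv",
                    index_label="transcript")
        means = summarize_variance(decomp)
        print(f"{name}: mean proportions "
              + ", ".join(f"{k.removeprefix('prop_')}={v:.3f}"
                          for k, v in means.items()))


if __name__ == "__main__":
    main()
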