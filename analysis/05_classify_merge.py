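"""Merge eQTLs across phenotypes, label cis/trans, estimate effect sizes.

Same-transcript records within 5.5 cM across control/SA/delta collapse to
one locus at their mean position; loci within 10 cM of their transcript's
genomic position (same chromosome) are cis, the rest trans. Effect size is
the R^2 of the phenotype on dosage at the consensus-nearest marker.
"""
from pathlib import Path

import pandas as pd

from plastiqtl import classify
from plastiqtl.core_io import (FLOAT_FMT, read_expression, read_genetic_map,
                               read_genotypes)
from plastiqtl.phenotypes import PhenotypeSet, build_phenotypes
from plastiqtl.scan import genotype_probabilities

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = BASE / "data"
    gmap = read_genetic_map(data / "map.csv")
    geno = read_genotypes(data / "genotypes.csv", gmap)
    ds = read_expression(data / "expression.tsv", data / "samples.tsv")
    eqtl = pd.read_csv(BASE / "eqtl" / "eqtl.tsv", sep="\t",
                       dtype={"transcript": str, "chromosome": str})
    genes = pd.read_csv(data / "gene_positions.tsv", sep="\t",
                        dtype={"transcript": str, "chromosome": str})
    genes = genes.rename(columns={"position_cM": "cM"})

    phen = build_phenotypes(ds)
    ril_ids = [g for g in phen.control.index if g in set(geno.lines)]
    ril_phen = PhenotypeSet(phen.control.loc[ril_ids], phen.SA.loc[ril_ids],
                            phen.delta.loc[ril_ids])
    probs = genotype_probabilities(geno, gmap).loc[ril_ids]

    merged = classify.merge_all(eqtl, window=5.5)
    classify.attach_cis_trans(merged, genes, window=10.0)
    classify.attach_effect_sizes(merged, probs, ril_phen, gmap)
    frame = classify.merged_to_frame(merged)
    out = BASE / "eqtl"
    frame.to_csv(out / "merged_eqtl.tsv", sep="\t", index=False,
                 float_format=FLOAT_FMT)

    summary = classify.summarize_cis_trans(merged)
    overall = summary["overall"]
    print(f"merged loci: {len(merged)} "
          f"({overall['n_cis']} cis, {overall['n_trans']} trans; "
          f"trans proportion {overall['trans_proportion']:.2f})")
    print(f"per transcript: {overall['cis_per_transcript']:.2f} cis, "
          f"{overall['trans_per_transcript']:.2f} trans")
    for subset, d in sorted(summary["per_membership"].items()):
        print(f"  membership {subset}: {d['n_cis'] + d['n_trans']} loci, "
              f"mean R^2 {d['mean_r2']:.3f}")


if __name__ == "__main__":
    main()
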