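"""Build the three expression phenotypes and quantify transgression.

Per genotype per transcript: mean control abundance, mean SA abundance, and
delta = (SA - control)/((SA + control)/2). Runs the transcriptome PCA over
genotype means and summarises, per transcript, the fraction of RILs falling
strictly outside the parental range for each phenotype — the transgressive-
segregation signal expected from opposing-sign allele pairs.
"""
from pathlib import Path

from plastiqtl.core_io import read_expression, write_table
from plastiqtl.phenotypes import (build_phenotypes, pca_transcriptomes,
                                  transgression_summary)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = read_expression(BASE / "data" / "expression.tsv",
                         BASE / "data" / "samples.tsv")
    out = BASE / "phenotypes"
    out.mkdir(parents=True, exist_ok=True)
    phen = build_phenotypes(ds)
    for name, table in phen.items():
        write_table(table, out / f"phenotype_{name}.tsv")
    scores, _, evr = pca_transcriptomes(phen.control.dropna(), n_components=2)
    write_table(scores, out / "pca_scores_control.tsv")
    summary = transgression_summary(phen, ("Bay", "Sha"))
    write_table(summary, out / "transgression.tsv", index_label="transcript")
    print(f"PC1/PC2 explained variance: {evr[0]:.3f}/{evr[1]:.3f}")
    for name in ("control", "SA", "delta"):
        frac = summary[f"{name}_frac_outside"].mean()
        print(f"{name}: mean transgressive RIL fraction {frac:.3f}")


if __name__ == "__main__":
    main()
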