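"""Build the demo RIL population and treatment-responsive transcriptome.

210 F8 lines on five chromosomes (100/70/80/80/100 cM, markers every 2 cM),
300 transcripts with 20 cis effects, 40 dispersed trans effects, a
60-target pleiotropic hotspot on chromosome 2 at 48 cM, 20% opposing-sign
pairs, two treatments x two replicates. Writes the population, expression
and planted ground truth under results/data/.
"""
from pathlib import Path

import plastiqtl as pq
from plastiqtl.core_io import (FLOAT_FMT, write_expression, write_genetic_map,
                               write_genotypes)

SEED = 20260928
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gmap = pq.make_map([100, 70, 80, 80, 100], 2.0)
    geno = pq.simulate_ril_genotypes(gmap, 210, seed=SEED)
    arch = pq.plant_architecture(
        gmap, 300,
        pq.ArchitectureConfig(n_cis=20, n_trans=40,
                              hotspots=[("2", 48.0, 60)],
                              opposing_fraction=0.2, min_effect=0.5),
        seed=SEED + 1)
    dataset = pq.simulate_expression(geno, arch, n_replicates=2,
                                     seed=SEED + 2)
    write_genetic_map(gmap, OUT / "map.csv")
    write_genotypes(geno, OUT / "genotypes.csv")
    write_expression(dataset, OUT / "expression.tsv", OUT / "samples.tsv")
    arch.to_frame().to_csv(OUT / "planted_truth.tsv", sep="\t", index=False,
                           float_format=FLOAT_FMT)
    arch.transcript_positions.to_csv(OUT / "gene_positions.tsv", sep="\t",
                                     index=False, float_format=FLOAT_FMT)
    n_plast = sum(e.is_plasticity for e in arch.effects)
    print(f"wrote {geno.n_lines} lines x {gmap.n_markers} markers, "
          f"{len(dataset.transcripts)} transcripts, "
          f"{len(arch.effects)} planted effects ({n_plast} plasticity) "
          f"to {OUT}")


if __name__ == "__main__":
    main()
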