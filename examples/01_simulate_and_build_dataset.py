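"""Simulate a genome with planted splice sites and build a donor dataset.

The simulator emits FASTA + GFF3 with known gene models; the dataset
pipeline derives the annotated donor sites, cuts 402-nt windows (site
dinucleotide at positions 201-202), mines GT-bearing negative windows,
deduplicates, balances and splits 60/15/25.
"""

import tempfile
from pathlib import Path

import resplice as rs

with tempfile.TemporaryDirectory() as tmp:
    sim = rs.simulate_genome(rs.SimulatorConfig.tiny(seed=0))
    paths = sim.write(Path(tmp) / "genome")
    print(f"simulated {len(sim.genomes)} contigs, "
          f"{len(sim.truth.genes)} genes, {len(sim.truth.sites)} planted sites")

    splits, manifest = rs.build_dataset(
        paths["fasta"], paths["gff"], site_type="donor", seed=0
    )

print(f"annotated donor sites : {manifest['n_annotated_sites']}")
print(f"positive windows      : {manifest['n_positive_windows']} "
      f"({manifest['n_rejected_windows']} rejected at contig edges/N)")
print(f"negative candidates   : {manifest['n_negative_candidates']} genome-wide GT positions")
print(f"train/val/test sizes  : {manifest['split_sizes']}")

example = splits.train[0]
print(f"\nfirst training window: {example.label} at {example.seq_id}:{example.position}")
print(f"  centre (positions 199-206): ...{example.sequence[198:206]}...")
print("  -> positions 201-202 hold the GT dinucleotide for donor windows,")
print("     for true sites surrounded by the planted consensus context.")
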