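"""File round trip: write a peptide list, run a scan, inspect the bundle.

The same bundle is produced by the command line:
    pepgibbs -f peptides.txt -o out -g 1-3 -seeds 3 -seed 1
"""

import tempfile
from pathlib import Path

from pepgibbs import Config, filter_peptides, read_peptides, run_scan, \
    validate_config, write_bundle
from pepgibbs.synthetic import canonical_benchmark, write_benchmark

workdir = Path(tempfile.mkdtemp())
peptides, truth = canonical_benchmark(seed=42)
write_benchmark(peptides, truth, workdir / "peptides.txt",
                workdir / "truth.tsv")

loaded = read_peptides(workdir / "peptides.txt")
config = validate_config(Config(cluster_range=(1, 3), num_seeds=3,
                                num_T_steps=10, rng_seed=1))
kept, dropped = filter_peptides(loaded, config)
print(f"read {len(loaded)} peptides, kept {len(kept)}, "
      f"dropped {len(dropped)}")

scan = run_scan(kept, config)
manifest = write_bundle(scan, workdir / "out", len(loaded), len(dropped))
print(f"suggested number of clusters: {scan.suggested_g}")
print("bundle files:")
for p in manifest["paths"]:
    print("  ", p.name)
print("\nKLD report:")
print((workdir / "out" / "kld.tsv").read_text())
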