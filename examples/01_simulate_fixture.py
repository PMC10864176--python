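"""Simulate a paired snRNA/snATAC dataset with planted regulatory programs.

The generator puts nuclei on a bifurcating latent trajectory, plants
TF -> enhancer -> target-gene programs on a synthetic chromosome and draws
negative-binomial RNA and Poisson ATAC counts. The fixture written at the end
is plain text (Matrix Market + TSV + BED) and fully determined by the seed.
"""
import tempfile
from pathlib import Path

from egrnkit import SimConfig, simulate_multiome
from egrnkit.io import write_fixture

config = SimConfig(seed=1)
pm, truth = simulate_multiome(config)

print(f"RNA matrix: {pm.rna.n_vars} genes x {pm.rna.n_obs} nuclei, "
      f"median depth {pm.rna.X.sum(axis=1).mean():.0f}")
print(f"ATAC matrix: {pm.atac.n_vars} peaks x {pm.atac.n_obs} nuclei")
print(f"planted programs: {len(truth.tf_home_cluster)} TFs, "
      f"{len(truth.planted_links)} enhancer-gene pairs")
print("TF home clusters:", truth.tf_home_cluster)

out = Path(tempfile.mkdtemp()) / "fixture"
write_fixture(pm, truth, config, out)
print(f"\nfixture written to {out}:")
for p in sorted(out.rglob("*")):
    if p.is_file():
        print("  ", p.relative_to(out))
# Every file is byte-identical across runs with the same config + seed.
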