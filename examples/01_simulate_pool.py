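"""Simulate a randomized-flank substrate pool and write hairpin bisulfite reads.

Builds a pool of duplexes whose central CpG is flanked by 10 random bases
on each side, methylates them under a known preference model (an enzyme
that favours G at the +1 position), and writes the resulting hairpin
bisulfite FASTQ plus a ground-truth table.
"""

from pathlib import Path

from methylflank import (
    PreferenceModel,
    SubstrateLayout,
    emit_hairpin_fastq,
    generate_pool,
    simulate_methylation,
)
from methylflank.simpool import write_truth_table

out = Path("scratch/example01")
out.mkdir(parents=True, exist_ok=True)

layout = SubstrateLayout()  # 20-nt arms, 10-nt random flanks, central CG
pool = generate_pool(2000, layout.flank_len, "CG", seed=1, layout=layout)

# ground truth: 60% methylation with G at +1, 20% otherwise
model = PreferenceModel(kind="positional", base_rate=0.2, weights={1: {"G": 3.0}})
outcomes = simulate_methylation(pool, model, seed=2)

n = emit_hairpin_fastq(pool, outcomes, conversion_rate=0.998,
                       inappropriate_conversion=0.002, seq_error=0.001,
                       seed=3, out=out / "reads.fastq", layout=layout)
write_truth_table(pool, outcomes, out / "truth.tsv", seed=1)

n_meth = sum(o.target_methylated for o in outcomes)
print(f"molecules simulated : {len(pool)}")
print(f"strand events       : {len(outcomes)} (top + bottom per CpG)")
print(f"methylated events   : {n_meth} ({100 * n_meth / len(outcomes):.1f}%)")
print(f"reads written       : {n} -> {out / 'reads.fastq'}")
# The methylated fraction sits between 20% and 60%: 1/4 of strand contexts
# carry the favoured +1 G, so the pool-wide mean is 0.25*0.6 + 0.75*0.2 = 0.3.
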