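"""Call a damage-masked consensus genome, letting the contamination estimate
choose between all fragments and deaminated fragments only."""

import numpy as np

from paleomito import alignment, consensus, damage, simulate
from paleomito.consensus import ConsensusParams

ref = simulate.simulate_reference(16_569, seed=1)
frags, truth = simulate.simulate_fragments(
    ref,
    simulate.DamageModel(),
    simulate.LibraryConfig(n_fragments=18_000, contamination_fraction=0.2, seed=5),
)
frags = alignment.deduplicate(alignment.filter_fragments(frags))

est = damage.estimate_contamination(frags, ref, error_rate=0.001, seed=6)
mode = consensus.select_mode(est)  # <5% -> all fragments, otherwise deaminated only
print(f"contamination estimate {est.point:.3f} -> mode: {mode}")

flags = damage.deaminated_flags(frags, ref)
genome = consensus.call_consensus(
    frags, ref, ConsensusParams(mode=mode), deaminated_flags=flags
)
print(f"called {genome.n_called}/{len(genome)} sites; {genome.n_missing} N")

called = np.array(list(genome.sequence))
truth_seq = np.array(list(ref.sequence))
acc = (called[genome.called] == truth_seq[genome.called]).mean()
print(f"accuracy at called sites vs simulation truth: {acc:.5f}")
# Sites fail (N) when fewer than 5 fragments remain after masking terminal
# C->T observations, or when the top base has under 80% support.
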