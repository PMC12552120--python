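"""The four similarity metrics and the combined S score for complex pairs.

A pair of complexes is compared by ligand chemistry (count-fingerprint
Tanimoto), protein fold (TM-score, best of both length normalizations),
ligand placement after superposing the proteins (nearest-neighbour RMSD)
and affinity difference (|delta pK|). S = TM + Tanimoto + (1 - RMSD) - dpK
summarizes the pair; a self-comparison scores exactly 3.
"""

from gems import KabschAligner, pair_similarity
from gems.fixtures import ScenarioSpec, make_scenario

scenario = make_scenario(ScenarioSpec(seed=1))
aligner = KabschAligner()

record = scenario.train[0]
self_sim = pair_similarity(record, record, aligner)
print(f"{record.id} vs itself: Tanimoto={self_sim.tanimoto:.3f} "
      f"TM={self_sim.tm_score:.3f} RMSD={self_sim.ligand_rmsd:.3f} "
      f"dpK={self_sim.delta_pk:.3f} -> S={self_sim.s_score:.3f}")

# a planted leaked pair: a training complex that is a structural copy of a
# test complex with a nearby label -- S approaches 3
leak_id = sorted(scenario.planted_overlap_ids)[0]
train = next(r for r in scenario.train if r.id == leak_id)
test = next(r for r in scenario.test if r.id == f"te{leak_id[-2:]}")
sim = pair_similarity(train, test, aligner)
print(f"{train.id} vs {test.id} (planted leak): S={sim.s_score:.3f}")

# an unrelated pair: different scaffold, different fold, S is low
other = scenario.train[-1]
sim = pair_similarity(other, test, aligner)
print(f"{other.id} vs {test.id} (unrelated):    S={sim.s_score:.3f}")
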