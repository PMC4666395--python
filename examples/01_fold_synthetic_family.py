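"""Secondary structure prediction on a synthetic riboswitch-like family.

Generates an alignment with planted helices (strong Watson-Crick
covariation) and weaker tertiary couplings, scores column pairs with
mean-field DCA (Fapc) and mutual information, folds the target with the
generalized Nussinov dynamic program, and evaluates against the planted
structure. Sensitivity = fraction of planted pairs recovered; precision =
fraction of predicted pairs that are planted.
"""

from rnadca.alignment import build_column_map
from rnadca.experiments import all_scores
from rnadca.secondary import build_pair_scores, evaluate_structure, nussinov
from rnadca.structures import CuratedStructure, pairs_to_dotbracket
from rnadca.synthetic import GeneratorSpec, sample_potts_alignment

spec = GeneratorSpec(n=70, M=500, seed=42, burn_in=300)
aln, truth = sample_potts_alignment(spec)
cmap = build_column_map(aln, "target")
ref = CuratedStructure(truth["secondary_pairs"], sequence=cmap.target_sequence)

print(f"family: {aln.M} sequences x {aln.L} columns, "
      f"{len(ref.base_pairs)} planted base pairs")
print("target   ", cmap.target_sequence)
print("planted  ", pairs_to_dotbracket(ref.base_pairs, aln.L))

for sm in all_scores(aln):
    pred = nussinov(build_pair_scores(sm, cmap))
    rep = evaluate_structure(pred, ref)
    print(f"{sm.kind:>6}   ", pairs_to_dotbracket(pred.pairs, aln.L))
    print(f"         sensitivity {rep.sensitivity:.3f}  "
          f"precision {rep.precision:.3f}  "
          f"(TP {rep.tp} FP {rep.fp} FN {rep.fn})")
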