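"""Plant known transposable elements in a synthetic genome and find them.

Builds the standard 100 kb fixture (10 LTR retrotransposons at divergences
0.01-0.10, 10 MITEs, 5 canonical Helitrons, 5 LINE surrogates), runs each
structural detector, and prints per-class recall at <= 10 bp boundary error.
A recall of 10/10 means every planted element of that class was recovered
with both boundaries within 10 bp of the planted truth.
"""

from te_prospector import class2_detect, ltr_detect, nonltr_detect
from te_prospector.evaluate import overlap_recall, recall
from te_prospector.synthetic import standard_fixture

syn = standard_fixture(seed=1)
print(f"genome: {syn.genome.length} bp with {len(syn.truth)} planted elements")

cands = ltr_detect.find_ltr_candidates(syn.genome)
print("LTR-RT   recall %d/%d" % recall(syn.truth, [c.element for c in cands], "LTR_RT"))

mites = class2_detect.find_mites(syn.genome)
print("MITE     recall %d/%d" % recall(syn.truth, [m.element for m in mites], "MITE"))

five, three = class2_detect.score_helitron_termini(syn.genome)
hels = class2_detect.pair_helitrons(five, three, syn.genome)
print("Helitron recall %d/%d" % recall(syn.truth, [h.interval for h in hels], "HELITRON"))

lines = nonltr_detect.detect_nonltr(syn.genome)
print(
    "LINE     recall %d/%d (by coding ORF containment)"
    % overlap_recall(syn.truth, [e.orf.interval for e in lines], "LINE", min_overlap=0.3)
)
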