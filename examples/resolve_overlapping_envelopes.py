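"""Resolve the four canonical overlapping-envelope configurations.

Two fragment ions whose isotopic envelopes interleave or share peaks
cannot be separated by greedy template matching; the cluster graph
represents both hypotheses and the highest-score path selects the pair.
"""

from deisograph import ARCHETYPES, deisotope_spectrum, overlap_archetype

DESCRIPTIONS = {
    "interleaved": "two 1+ envelopes threaded through each other, no shared peak",
    "shared-two": "two 1+ triples sharing their two central peaks",
    "shared-one": "a 1+ triple whose last peak starts a second 1+ pair",
    "mixed-charge": "a 2+ triple sharing its second peak with a 1+ triple",
}

for kind in ARCHETYPES:
    spectrum, truth = overlap_archetype(kind)
    ions = [i for i in deisotope_spectrum(spectrum) if len(i.member_indices) > 1]
    print(f"{kind}: {DESCRIPTIONS[kind]}")
    print("  planted:", [(round(c.mono_mz, 4), f"{c.charge}+") for c in truth])
    print("  resolved:", [(round(i.mono_mz, 4), f"{i.charge}+") for i in ions])
    print()
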