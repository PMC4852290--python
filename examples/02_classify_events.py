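"""Classify structural changes in two worked scenarios.

Scenario 1: a Brassicaceae-like intron loss — one gene's fifth exon (84 bp)
aligns perfectly to the fifth (42 bp) plus sixth (42 bp) exon of its
homolog, with identical coding sequence.

Scenario 2: stop-codon readthrough — two point substitutions break the
ancestral stop codon, recruiting the next in-frame 15 bp of former 3' UTR
into the coding sequence.
"""

from exevol import emit_fixture
from exevol.events import detect_intron_change, detect_stop_codon_events

fs, tree, _ = emit_fixture("brassicaceae_intron_loss")
events = detect_intron_change(fs.models["SEP12_ref"],
                              fs.models["SEP12_brassicaceae"])
for ev in events:
    print(f"intron change at exon {ev.exon_index}: merged exon of "
          f"{ev.detail['merged_exon_length']} bp "
          f"(partner exons {ev.detail['partner_exon_lengths']})")

fs, tree, _ = emit_fixture("paleoAP1_stop_loss")
events = detect_stop_codon_events(fs.models["paleoAP1"],
                                  fs.models["SEP_ref"])
for ev in events:
    print(f"{ev.mechanism}: {ev.length_bp} bp of new coding sequence "
          f"(broken stop {ev.detail['broken_stop']} -> "
          f"{ev.detail['replacement']})")

# Expected output: the 84-bp merged exon (42 + 42) diagnostic of intron
# loss, and a 15-bp exonization driven by loss of the stop codon.
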