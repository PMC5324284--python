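"""Design a short tandem target mimic (STTM) knockdown construct.

Builds the bulged binding site (reverse complement with a CTA bulge between
the bases pairing miRNA positions 10 and 11), assembles the HindIII/PstI-
flanked insert with the 48-nt spacer, derives the complementary long primers,
simulates the double digestion, and cross-checks the design against the
target-prediction module.
"""

from etiomir import sttm

MIR1432 = "CUCAGGAGAGAUGACACCGAC"

site = sttm.design_binding_site(MIR1432)
print(f"mature miR1432 (21 nt): {MIR1432}")
print(f"binding site   ({len(site)} nt): {site}")

construct = sttm.build_construct(MIR1432, mirna_id="miR1432")
print(f"\nfull insert ({len(construct.full_insert)} nt):")
print(f"  {construct.full_insert}")
print(f"forward primer: {construct.forward_primer[:30]}...")
print(f"reverse primer: {construct.reverse_primer[:30]}...")
print(f"notes: {construct.notes}")

report = sttm.verify_construct(construct, MIR1432)
print(f"\nverification: mimic={report['is_mimic']} "
      f"(sites={report['n_mimic_sites']}), cleavage site={report['is_cleavage_site']}")
print(f"HindIII/PstI digestion -> {report['n_fragments']} fragments:")
for frag in report["fragments"]:
    print(f"  {len(frag):>3} nt  {frag if len(frag) < 60 else frag[:57] + '...'}")
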