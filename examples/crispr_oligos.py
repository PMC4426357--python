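"""Walk through the cdc-25.2 CRISPR repair-oligo design.

Two 137-nt HDR donors differ at exactly one base: the "rescue" donor
converts the mutant T back to wild-type C, the "recreation" donor installs
the mutation into wild type.  Both carry the same silent edit that destroys
the guide's NGG PAM (so Cas9 cannot re-cut the repaired locus) and, as a
bonus, that edit creates an EaeI (YGGCCR) site usable as a digest screen.
"""

from hawmap import locate_protospacer, scan_restriction_sites, verify_repair_oligo
from hawmap.fixtures import load_crispr_sequences

seqs = load_crispr_sequences()
guide = seqs["guide"]
rescue = seqs["rescue_oligo"]
recreation = seqs["recreation_oligo"]

print(f"guide ({len(guide)} nt): {guide}")

diff = verify_repair_oligo(rescue, recreation)
(pos, a, b) = diff.edits[0]
print(
    f"\nrescue vs recreation: {len(diff.edits)} difference at oligo "
    f"position {pos} ({a} vs {b})"
)
print(f"5' homology flank: {diff.arm5} nt, 3' flank: {diff.arm3} nt")

print("\nguide+NGG sites:")
print(f"  edited donor:        {locate_protospacer(guide, rescue) or 'none'}")
restored = rescue[:85] + "G" + rescue[86:]  # undo the silent PAM edit
site = locate_protospacer(guide, restored)[0]
print(
    f"  PAM restored (G86):  {site.strand} strand {site.start}-{site.end}, "
    f"PAM {site.pam}, blunt cut after base {site.cut_after}"
)

print("\nEaeI (YGGCCR) diagnostic sites:")
print(f"  edited donor:        {scan_restriction_sites(rescue, 'EaeI')}")
print(f"  PAM restored:        {scan_restriction_sites(restored, 'EaeI') or 'none'}")
print("-> an EaeI digest distinguishes edited from unedited animals")
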