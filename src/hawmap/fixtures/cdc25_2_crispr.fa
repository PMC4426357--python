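>guide cdc-25.2 protospacer, 19 nt, targets the non-coding strand
ATGTCTCTCAATGTTTCGG
>rescue_oligo 137-nt HDR donor converting the mutant T716 back to wild-type C, with the silent PAM-destroying edit
ATGGGTAGCGGCAATCAATGAGAATATACTTGTCATCAAATTCTTTTTCAGAGAGTCGGAAAAAGATGTCTCTCAATGTTTCGGCCGTGATTCTTCTGAAGCCTTTCGAGGATTCCTTTGCAACAGTTTTGAGGTGG
>recreation_oligo 137-nt HDR donor installing C716T into wild type, same silent PAM-destroying edit
ATGGGTAGCGGCAATCAATGAGAATATACTTGTCATCAAATTCTTTTTCAAAGAGTCGGAAAAAGATGTCTCTCAATGTTTCGGCCGTGATTCTTCTGAAGCCTTTCGAGGATTCCTTTGCAACAGTTTTGAGGTGG
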