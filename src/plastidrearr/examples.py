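"""Worked-example junction sequences.

Three sequenced recombinant junctions from high-light-induced plastid DNA
rearrangements around the Arabidopsis psbD locus, each given as the two
parental 30/31-mers flanking the new join and the recombinant amplicon
across it.  They are small, real-world inputs for
:func:`plastidrearr.annotate.find_direct_repeat` and are used in the
package's documentation and checks.

Each entry: (parent_a, parent_b, recombinant, repeat_length, mismatches)
for exact matching (``max_mismatch=0``).
"""

__all__ = ["PSBD_JUNCTIONS"]

PSBD_JUNCTIONS = {
    # rpoC2 joined to the non-coding spacer between trnT-ACC and psbD;
    # the parents share an 11 bp direct repeat at the junction
    "rpoC2_trnT_psbD": (
        "AATTGTAATTAGAGTATTTTTTTTTATTGAT",
        "CTAGAGAAAGAGAGTATTTTTGCAAAGTAAT",
        "AATTGTAATTAGAGTATTTTTGCAAAGTAAT",
        11,
        0,
    ),
    # trnT-ACC/psbD spacer joined to the petA-psbJ spacer; 10 bp repeat
    "trnT_psbD_petA_psbJ": (
        "CCCGTCAACTAAAAAAAGGGTATAAAAGGA",
        "ACACGCGCCGAAAAAAAGGGGGAACCATAAA",
        "CCCGTCAACTAAAAAAAGGGGGAACCATAAA",
        10,
        0,
    ),
}
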