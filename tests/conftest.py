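import numpy as np
import pytest

from nmthc.io_formats import AlignmentRecord, ExtendedCigar, SequenceRecord, parse_extended_cigar


@pytest.fixture(scope="session")
def worked_example():
    """The three-short-read pileup scenario: substitutions at long-read
    positions 9-10 (seen by two reads), deletions at 11-13 (all reads),
    and a 4-base insertion AACA between positions 19 and 20 (all reads).

    The long read is 21 bp; its bases at the edited sites are fixed by the
    scenario (G,T at 9,10; A,T,C at 11-13), the rest arbitrary.
    """
    #         123456789012345678901
    lr_bases = "CATGACGAGTATCGCTACGTC"
    long_read = SequenceRecord(id="LR", bases=lr_bases)

    def query_for(cigar: ExtendedCigar) -> str:
        # short reads carry the *corrected* bases: A,C at 9,10; nothing for
        # 11-13; AACA inserted after 19
        corrected = {9: "A", 10: "C"}
        out = []
        pos = cigar.start
        for n, code in cigar.ops:
            if code == "M":
                out.append(lr_bases[pos - 1 : pos - 1 + n])
                pos += n
            elif code == "S":
                out.append("".join(corrected[pos + i] for i in range(n)))
                pos += n
            elif code == "D":
                pos += n
            else:
                out.append("AACA")
        return "".join(out)

    cigars = {
        "SR1": parse_extended_cigar("5:4M2S3D6M4I1M"),
        "SR2": parse_extended_cigar("7:2M2S3D6M4I1M"),
        "SR3": parse_extended_cigar("11:3D6M4I1M"),
    }
    alignments = [
        AlignmentRecord(
            short_read_id=name,
            long_read_id="LR",
            cigar=cig,
            query_bases=query_for(cig),
        )
        for name, cig in cigars.items()
    ]
    return long_read, alignments


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
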