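import numpy as np
import pytest

from ilsscan.msa import AlignmentBlock, AlignmentWindow, GenomeAlignment

SPECIES4 = ["human", "chimpanzee", "bonobo", "gorilla"]
SPECIES5 = SPECIES4 + ["orangutan"]


def make_window(cols, species=SPECIES4, chrom="chr1", start=0):
    """Build a window from per-column tuples ordered like ``species``."""
    seqs = {
        sp: "".join(col[i] for col in cols) for i, sp in enumerate(species)
    }
    n_aligned = sum(all(c not in "-N" for c in col) for col in cols)
    return AlignmentWindow(chrom=chrom, start=start, end=start + len(cols),
                          seqs=seqs, n_aligned_cols=n_aligned)


def make_alignment(seqs, species=SPECIES4, chrom="chr1", ref_start=0):
    """Single-block GenomeAlignment from equal-length gapped strings."""
    block = AlignmentBlock(chrom=chrom, ref_start=ref_start,
                           seqs={sp: seqs[i] for i, sp in enumerate(species)})
    ga = GenomeAlignment(species_ids=list(species), blocks=[block])
    ga.validate()
    return ga


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
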