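"""Bundled small datasets."""

from importlib import resources

from .sumstats import SumstatRecord, read_sumstats


def load_kyn_instruments() -> list[SumstatRecord]:
    """The six published lead SNPs for circulating kynurenine.

    Genome-wide-significant lead variants from the KORA-TwinsUK metabolite
    GWAS meta-analysis (7824 Europeans), with per-reference-allele effects on
    plasma kynurenine. These are the discovery instruments the downstream
    PheWAS/PRS/MR analyses build on.
    """
    path = resources.files("kynscan.data").joinpath("kyn_instruments.tsv")
    with resources.as_file(path) as p:
        return read_sumstats(p)
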