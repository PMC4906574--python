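import pytest

from sheetcheck import SheetGrid, build_qiime_ruleset, build_srgd_ruleset

QIIME_HEADER = ("#SampleID", "BarcodeSequence", "LinkerPrimerSequence", "Description")


def make_qiime_grid(data_rows, header=QIIME_HEADER):
    """A small QIIME-shaped grid from explicit data rows (tuples of str)."""
    return SheetGrid(
        cells=(tuple(header),) + tuple(tuple(r) for r in data_rows),
        source_dialect="tsv",
    )


@pytest.fixture(scope="session")
def qiime_ruleset():
    return build_qiime_ruleset()


@pytest.fixture(scope="session")
def srgd_ruleset():
    return build_srgd_ruleset()
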