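"""Bundled reference data."""

from importlib import resources

from .grid import read_clue_list


def quiet_please_clues() -> dict[str, str]:
    """The transcribed 78-clue list of the study's 15x15 test puzzle.

    Labels map to clue text; the list carries no grid (the published
    figure was not machine-readable), so it serves as a clue-parsing
    reference, not a solvable puzzle.
    """
    path = resources.files("crossmind.data") / "quiet_please_clues.tsv"
    with resources.as_file(path) as p:
        return read_clue_list(p)
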