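"""Shared constants: founder codes, timepoint grids and stage windows."""

FOUNDER_CODES = ("AK", "BE", "TC", "MI", "SU", "TK", "HO", "RU")
FOUNDER_LABELS = tuple(range(1, 9))

CODE_TO_LABEL = {code: i + 1 for i, code in enumerate(FOUNDER_CODES)}
LABEL_TO_CODE = {i + 1: code for i, code in enumerate(FOUNDER_CODES)}

STAGES = ("tillering", "heading", "maturation")

# Days-after-transplanting observation grids, one per field season.
YEAR_DATS = {
    "2019": (40, 56, 69, 83, 97, 111),
    "2018": (39, 54, 68, 83, 97, 113),
}

# Cross-year pairing of the six observation timepoints (2019 DAT, 2018 DAT).
DEFAULT_DAT_PAIRS = ((40, 39), (56, 54), (69, 68), (83, 83), (97, 97), (111, 113))

# Developmental stage of each paired timepoint, in grid order.
PAIR_STAGES = (
    "tillering",
    "tillering",
    "heading",
    "heading",
    "maturation",
    "maturation",
)

TIMECOURSE_TRAITS = ("CH", "VF", "minus_a_star")
ENDPOINT_TRAITS = ("CL", "PL", "PN", "PW", "SLW", "TW", "SDW")


def stage_of_dat(year: str, dat: int) -> str:
    """Developmental stage of a grid timepoint for the given year."""
    grid = YEAR_DATS[year]
    if dat not in grid:
        raise ValueError(f"DAT {dat} is not on the {year} observation grid {grid}")
    return PAIR_STAGES[grid.index(dat)]
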