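"""Categorical codes shared across the simulation.

Internally the population table stores small integer codes; these tuples
define the code -> label mapping.  Labels are what serialized output and
observer extracts show.
"""
from __future__ import annotations

import numpy as np

SEXES = ("Male", "Female")
SEX_MALE, SEX_FEMALE = 0, 1

# Composite race/ethnicity categories (OMB-style, Hispanic ethnicity takes
# precedence over any reported race).
RACE_ETHNICITIES = (
    "White",
    "Black",
    "Latino",
    "American Indian and Alaskan Native",
    "Asian",
    "Native Hawaiian and Other Pacific Islander",
    "Multiracial or Some Other Race",
)
RACE_LATINO = RACE_ETHNICITIES.index("Latino")

# Raw race codes as they appear in microdata, before compositing with the
# Hispanic-ethnicity flag.
MICRODATA_RACE_CODES = ("white", "black", "aian", "asian", "nhopi", "other", "multiracial")
_RACE_CODE_TO_COMPOSITE = {
    "white": "White",
    "black": "Black",
    "aian": "American Indian and Alaskan Native",
    "asian": "Asian",
    "nhopi": "Native Hawaiian and Other Pacific Islander",
    "other": "Multiracial or Some Other Race",
    "multiracial": "Multiracial or Some Other Race",
}

NATIVITIES = ("US-born", "Foreign-born")
NATIVITY_US, NATIVITY_FOREIGN = 0, 1

# Relationship to the household reference person (residential households only).
RELATIONSHIPS = (
    "Reference person",
    "Biological child",
    "Adopted child",
    "Stepchild",
    "Sibling",
    "Parent",
    "Grandchild",
    "Parent-in-law",
    "Child-in-law",
    "Other relative",
    "Roommate",
    "Foster child",
    "Other nonrelative",
)
REL_REFERENCE = 0
REL_BIO_CHILD = 1
REL_ADOPTED_CHILD = 2
REL_STEPCHILD = 3
REL_SIBLING = 4
REL_PARENT = 5
REL_GRANDCHILD = 6
REL_PARENT_IN_LAW = 7
REL_CHILD_IN_LAW = 8
REL_OTHER_RELATIVE = 9
REL_ROOMMATE = 10
REL_FOSTER_CHILD = 11
REL_OTHER_NONRELATIVE = 12
REL_NONE = -1  # group-quarters residents have no tracked relationship

RELATIONSHIP_TO_CODE = {name: i for i, name in enumerate(RELATIONSHIPS)}

# Child-type relationships (share a parent if one of them succeeds as
# reference person).
CHILD_RELATIONSHIPS = frozenset({REL_BIO_CHILD, REL_ADOPTED_CHILD, REL_STEPCHILD})
KIN_RELATIONSHIPS = frozenset(
    {
        REL_BIO_CHILD,
        REL_ADOPTED_CHILD,
        REL_STEPCHILD,
        REL_SIBLING,
        REL_PARENT,
        REL_GRANDCHILD,
        REL_PARENT_IN_LAW,
        REL_CHILD_IN_LAW,
        REL_OTHER_RELATIVE,
    }
)

# Household kinds: one residential kind plus six group-quarters kinds.
INSTITUTIONAL_GQ_KINDS = ("Carceral", "Nursing home", "Other institutional")
NONINSTITUTIONAL_GQ_KINDS = ("College", "Military", "Other noninstitutional")
HOUSEHOLD_KINDS = ("Residential",) + INSTITUTIONAL_GQ_KINDS + NONINSTITUTIONAL_GQ_KINDS
KIND_RESIDENTIAL = 0
INSTITUTIONAL_GQ_CODES = tuple(HOUSEHOLD_KINDS.index(k) for k in INSTITUTIONAL_GQ_KINDS)
NONINSTITUTIONAL_GQ_CODES = tuple(HOUSEHOLD_KINDS.index(k) for k in NONINSTITUTIONAL_GQ_KINDS)
GQ_KIND_CODES = INSTITUTIONAL_GQ_CODES + NONINSTITUTIONAL_GQ_CODES

# Simulant liveness.
STATUS_PRESENT, STATUS_DEAD, STATUS_EMIGRATED = 0, 1, 2
STATUSES = ("Present", "Dead", "Emigrated")

# Distinguished employment states.  Regular employers get ids >= 2; -1 marks
# simulants outside the labor force (children, not yet assigned).
EMPLOYER_NONE = -1
EMPLOYER_UNEMPLOYED = 0
EMPLOYER_MILITARY = 1
FIRST_REGULAR_EMPLOYER_ID = 2
MILITARY_EMPLOYER_NAME = "United States Armed Forces"

WORKING_AGE = 18.0

# International move types (used by both immigration and emigration).
MOVE_HOUSEHOLD = "household"
MOVE_GQ_PERSON = "gq_person"
MOVE_NON_REFERENCE = "non_reference_person"
INTERNATIONAL_MOVE_TYPES = (MOVE_HOUSEHOLD, MOVE_GQ_PERSON, MOVE_NON_REFERENCE)

# Domestic individual-move destinations.
DEST_NEW_HOUSEHOLD = "new_household"
DEST_JOIN_HOUSEHOLD = "join_household"
DEST_GQ = "group_quarters"
DOMESTIC_DESTINATIONS = (DEST_NEW_HOUSEHOLD, DEST_JOIN_HOUSEHOLD, DEST_GQ)

# Five-year age groups 0-4 ... 80-84, 85+.
AGE_GROUP_LOWER_BOUNDS = tuple(range(0, 90, 5))
N_AGE_GROUPS = len(AGE_GROUP_LOWER_BOUNDS)

DAYS_PER_YEAR = 365.25


def age_group_index(ages) -> np.ndarray:
    """Map ages in years (scalar or array) to 5-year age-group indices, 85+ last."""
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 0):
        raise ValueError("ages must be non-negative")
    return np.minimum(ages // 5, N_AGE_GROUPS - 1).astype(np.int64)
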