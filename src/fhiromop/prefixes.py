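"""Resource-type prefixes used to qualify FHIR ids inside the OMOP target.

The FHIR logical id is only unique per resource type, so every id/identifier
stored in the target is qualified with a fixed three-letter prefix.  ``car``
is an internal prefix for care-site rows, which are keyed by the encounter's
service-provider identifier rather than by a FHIR resource of their own.
"""

from __future__ import annotations

PREFIX_FOR_TYPE: dict[str, str] = {
    "Patient": "pat",
    "Encounter": "enc",
    "Condition": "con",
    "Observation": "obs",
    "Procedure": "pro",
    "Medication": "med",
    "MedicationAdministration": "mea",
    "MedicationStatement": "mes",
}

#: internal prefix for care_site rows (derived from Encounter.serviceProvider)
CARE_SITE_PREFIX = "car"

TYPE_FOR_PREFIX: dict[str, str] = {v: k for k, v in PREFIX_FOR_TYPE.items()}
# care-site tracking rows are routed to the Encounter tracking table
TYPE_FOR_PREFIX[CARE_SITE_PREFIX] = "Encounter"

RESOURCE_TYPES: tuple[str, ...] = tuple(PREFIX_FOR_TYPE)


def prefix_of(qualified_id: str) -> str:
    """Return the three-letter prefix of a qualified id like ``con-c9``."""
    head, sep, _ = qualified_id.partition("-")
    if sep != "-" or head not in TYPE_FOR_PREFIX:
        raise ValueError(f"no registered prefix on qualified id {qualified_id!r}")
    return head
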