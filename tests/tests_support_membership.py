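"""Shared fixture: the published signature memberships of 28 candidate
miRNAs, from which the 19- and 14-member candidate signatures and the
7-miRNA hub set are reconstructed."""

MEMBERSHIP = {
    "hsa-miR-193b-5p": "19- and 7-miRNA",
    "hsa-miR-31-3p": "19- and 7-miRNA",
    "hsa-miR-31-5p": "19- and 7-miRNA",
    "hsa-miR-550a-5p": "19- and 7-miRNA",
    "hsa-miR-196b-5p": "19-, 14-miRNA and 7-miRNA",
    "hsa-miR-584-5p": "19-, 14-miRNA and 7-miRNA",
    "hsa-miR-193b-3p": "14- and 7-miRNA",
    "hsa-miR-30d-5p": "19- and 14-miRNA",
    "hsa-miR-582-3p": "19- and 14-miRNA",
    "hsa-miR-9-5p": "19 and 14-miRNA",
    "hsa-let-7c-3p": "19-miRNA",
    "hsa-miR-138-5p": "19-miRNA",
    "hsa-miR-196a-5p": "19-miRNA",
    "hsa-miR-203a-3p": "19-miRNA",
    "hsa-miR-215-5p": "19-miRNA",
    "hsa-miR-2355-3p": "19-miRNA",
    "hsa-miR-30d-3p": "19-miRNA",
    "hsa-miR-4709-3p": "19-miRNA",
    "hsa-miR-548b-3p": "19-miRNA",
    "hsa-miR-675-3p": "19-miRNA",
    "hsa-miR-135b-5p": "14-miRNA",
    "hsa-miR-187-3p": "14-miRNA",
    "hsa-miR-192-5p": "14-miRNA",
    "hsa-miR-210-3p": "14-miRNA",
    "hsa-miR-29b-2-5p": "14-miRNA",
    "hsa-miR-3065-3p": "14-miRNA",
    "hsa-miR-375-3p": "14-miRNA",
    "hsa-miR-708-5p": "14-miRNA",
}


def published_membership_fixture():
    """(hub_candidates, 19-signature, 14-signature, expected 7 hubs)."""
    sig19 = {m for m, s in MEMBERSHIP.items() if "19" in s}
    sig14 = {m for m, s in MEMBERSHIP.items() if "14" in s}
    seven = {m for m, s in MEMBERSHIP.items() if "7-miRNA" in s}
    return set(seven), sig19, sig14, seven
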