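"""ISO 3166-1 alpha-3 country codes and the EU member-state pool.

Notification records identify countries by alpha-3 codes (``DEU``, ``IRN``,
...).  Validation is optional because surveillance extracts occasionally use
ad-hoc codes for territories or organisations.
"""

from __future__ import annotations

# ISO 3166-1 alpha-3 officially assigned codes.
ISO_ALPHA3: frozenset[str] = frozenset(
    """
    ABW AFG AGO AIA ALA ALB AND ARE ARG ARM ASM ATA ATF ATG AUS AUT AZE
    BDI BEL BEN BES BFA BGD BGR BHR BHS BIH BLM BLR BLZ BMU BOL BRA BRB
    BRN BTN BVT BWA CAF CAN CCK CHE CHL CHN CIV CMR COD COG COK COL COM
    CPV CRI CUB CUW CXR CYM CYP CZE DEU DJI DMA DNK DOM DZA ECU EGY ERI
    ESH ESP EST ETH FIN FJI FLK FRA FRO FSM GAB GBR GEO GGY GHA GIB GIN
    GLP GMB GNB GNQ GRC GRD GRL GTM GUF GUM GUY HKG HMD HND HRV HTI HUN
    IDN IMN IND IOT IRL IRN IRQ ISL ISR ITA JAM JEY JOR JPN KAZ KEN KGZ
    KHM KIR KNA KOR KWT LAO LBN LBR LBY LCA LIE LKA LSO LTU LUX LVA MAC
    MAF MAR MCO MDA MDG MDV MEX MHL MKD MLI MLT MMR MNE MNG MNP MOZ MRT
    MSR MTQ MUS MWI MYS MYT NAM NCL NER NFK NGA NIC NIU NLD NOR NPL NRU
    NZL OMN PAK PAN PCN PER PHL PLW PNG POL PRI PRK PRT PRY PSE PYF QAT
    REU ROU RUS RWA SAU SDN SEN SGP SGS SHN SJM SLB SLE SLV SMR SOM SPM
    SRB SSD STP SUR SVK SVN SWE SWZ SXM SYC SYR TCA TCD TGO THA TJK TKL
    TKM TLS TON TTO TUN TUR TUV TWN TZA UGA UKR UMI URY USA UZB VAT VCT
    VEN VGB VIR VNM VUT WLF WSM YEM ZAF ZMB ZWE
    """.split()
)

# EU-27 member states (2007 enlargement state of the union, GBR included).
# The surveillance system is EU-run: only member states act as detectors,
# while any country (member or not) may appear as a transgressor.
EU_MEMBER_STATES: frozenset[str] = frozenset(
    """
    AUT BEL BGR CYP CZE DEU DNK ESP EST FIN FRA GBR GRC HUN IRL ITA LTU
    LUX LVA MLT NLD POL PRT ROU SVK SVN SWE
    """.split()
)


def is_known_code(code: str) -> bool:
    """True if ``code`` is an officially assigned alpha-3 code."""
    return code in ISO_ALPHA3


def validate_codes(codes, allow_unknown: bool = False) -> list[str]:
    """Return the codes not in the ISO alpha-3 list.

    Raises ``ValueError`` listing the offenders unless ``allow_unknown``.
    """
    unknown = sorted({c for c in codes if c not in ISO_ALPHA3})
    if unknown and not allow_unknown:
        raise ValueError(
            "unknown ISO 3166-1 alpha-3 country code(s): " + ", ".join(unknown)
        )
    return unknown
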