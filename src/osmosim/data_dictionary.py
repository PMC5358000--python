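"""Names and units of every column written to time-series CSV output."""

COLUMN_DICTIONARY = {
    "time_min": ("min", "time since protocol start"),
    # integrated state
    "V_ic": ("L", "intracellular water"),
    "V_is": ("L", "interstitial water"),
    "V_pl": ("L", "plasma water"),
    "V_rbc": ("L", "red-cell volume (constant)"),
    "Na_ec": ("mmol", "extracellular exchangeable sodium"),
    "Osm_ic": ("mOsm", "intracellular osmole content (quasi-fixed)"),
    "Prot_pl": ("g", "plasma protein mass"),
    "Gut_w": ("L", "unabsorbed gastrointestinal water"),
    "Gut_Na": ("mmol", "unabsorbed gastrointestinal sodium"),
    "Bladder_v": ("L", "cumulative urine volume"),
    "CWI": ("L", "cumulative oral water intake"),
    "avp": ("pg/mL", "plasma arginine vasopressin"),
    "avp_store": ("pg", "neurohypophyseal AVP store"),
    "anp": ("relative", "atrial natriuretic peptide (1 = baseline)"),
    "pra": ("relative", "plasma renin activity (1 = baseline)"),
    "angII": ("relative", "angiotensin II (1 = baseline)"),
    "aldo": ("relative", "aldosterone (1 = baseline)"),
    "oro_drive": ("dimensionless", "accumulated oropharyngeal reflex drive"),
    "cum_iv_w": ("L", "cumulative intravenous water"),
    "cum_iv_na": ("mmol", "cumulative intravenous sodium"),
    "cum_oral_na": ("mmol", "cumulative oral sodium"),
    "cum_insensible": ("L", "cumulative insensible water loss"),
    "cum_urine_na": ("mmol", "cumulative urinary sodium"),
    # derived observables
    "serum_osm": ("mOsm/kg", "serum osmolality"),
    "serum_Na": ("mmol/L", "serum sodium concentration"),
    "hct": ("fraction", "hematocrit"),
    "prot_conc": ("g/dL", "plasma protein concentration"),
    "blood_volume": ("L", "plasma + red-cell volume"),
    "icf_osm": ("mOsm/kg", "intracellular osmolality"),
    "map_mmHg": ("mmHg", "mean arterial pressure"),
    "P_c": ("mmHg", "capillary hydrostatic pressure"),
    "P_i": ("mmHg", "interstitial hydrostatic pressure"),
    "P_ra": ("mmHg", "right-atrial pressure"),
    "tpr_mult": ("relative", "total peripheral resistance multiplier"),
    "baro_arterial": ("relative", "arterial baroreceptor activity"),
    "baro_cardiac": ("relative", "cardiac baroreceptor activity"),
    "GFR": ("mL/min", "glomerular filtration rate"),
    "RBF": ("mL/min", "renal blood flow"),
    "FF": ("fraction", "filtration fraction"),
    "tgf_mult": ("relative", "tubuloglomerular-feedback afferent multiplier"),
    "Na_MD": ("mmol/min", "macula-densa sodium delivery"),
    "urine_flow": ("mL/min", "urine flow"),
    "urine_Na": ("mmol/min", "urinary sodium excretion"),
    "urine_osm": ("mOsm/kg", "urine osmolality"),
    "urine_na_conc": ("mmol/L", "urinary sodium concentration"),
    "thirst": ("dimensionless", "thirst drive (after pre-absorptive relief)"),
    "drink_rate": ("mL/min", "ad-libitum drinking rate"),
    "oro_inhibition": ("fraction", "oropharyngeal AVP-secretion suppression, 1-exp(-oro_drive)"),
}


def describe(column: str) -> str:
    units, desc = COLUMN_DICTIONARY[column]
    return f"{column} [{units}]: {desc}"
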