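"""Straight-line transcriptions of the published requirement equations.

Deliberately independent of the package: every formula is written out
literally, term by term, with no shared code, so these serve as arithmetic
oracles for the implementation.
"""


def bt2017(bw, adg):
    # maintenance + (weight-dependent lysine cost per kg gain) * gain
    y = 16.664 + 0.0736 * bw - 0.0003 * bw * bw
    return 0.036 * bw ** 0.75 + y * adg


def nrc_basal_endogenous(dfi):
    return dfi * 0.417 * 0.88 * 1.1


def nrc_integument(bw):
    return 0.0045 * bw ** 0.75


def nrc_pd(bw, coeff=133.0):
    pd = coeff * (
        0.7078
        + 0.013764 * bw
        - 0.00014211 * bw * bw
        + 3.2698e-7 * bw * bw * bw
    )
    return pd if pd > 0 else 0.0


def nrc_lys_in_pd(pd):
    return (pd * 7.10) / 100.0


def nrc2012(bw, dfi, maximum_pd, coeff=133.0, adjustment="divide"):
    e = 0.75 + 0.002 * (maximum_pd - 147.7)
    maintenance = (nrc_basal_endogenous(dfi) + nrc_integument(bw)) / e
    growth = nrc_lys_in_pd(nrc_pd(bw, coeff)) / e
    factor = 1 + 0.0547 + 0.002215 * bw
    if adjustment == "divide":
        growth = growth / factor
    else:
        growth = growth * factor
    return maintenance + growth


def agpic_below_40(bw):
    lb = bw * 2.204622
    return 0.0000255654 * lb * lb - 0.0157978368 * lb + 4.4555073859


def agpic_above_40(bw):
    c = (
        -0.0000000031 * bw ** 4
        + 0.0000013234 * bw ** 3
        - 0.0002087068 * bw ** 2
        + 0.0142221655 * bw
        - 0.3126825057
    )
    return agpic_below_40(bw) + c * agpic_below_40(bw)


def agpic(bw):
    return agpic_below_40(bw) if bw <= 40.0 else agpic_above_40(bw)
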