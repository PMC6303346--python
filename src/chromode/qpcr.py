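"""ChIP-qPCR double normalization and RT-qPCR relative quantification.

Histone-mark enrichment is normalized first to input DNA and then to a
negative control region devoid of the modification, with the wild-type
value set to 1. Factor-binding enrichment is normalized first to the IgG
ChIP and then to the ratio at a housekeeping promoter (Hprt). Transcript
abundance uses the standard 2^(-ddCt) method.
"""

from __future__ import annotations

import numpy as np


def _check_positive(**quantities: float) -> None:
    for name, q in quantities.items():
        if not q > 0:
            raise ValueError(f"{name} must be > 0 (got {q})")


def histone_mark_enrichment(
    chip_q: float,
    input_q: float,
    negctrl_chip_q: float,
    negctrl_input_q: float,
    wt_reference_value: float = 1.0,
) -> float:
    """(chip/input) / (negctrl_chip/negctrl_input), then relative to WT.

    With ``wt_reference_value`` left at 1 the raw double-normalized value is
    returned; pass the WT sample's value to express a mutant sample on the
    WT = 1 scale.
    """
    _check_positive(
        chip_q=chip_q, input_q=input_q, negctrl_chip_q=negctrl_chip_q,
        negctrl_input_q=negctrl_input_q, wt_reference_value=wt_reference_value,
    )
    return (chip_q / input_q) / (negctrl_chip_q / negctrl_input_q) / wt_reference_value


def ezh2_binding_enrichment(
    ezh2_chip_q: float,
    igg_chip_q: float,
    hprt_ezh2_q: float,
    hprt_igg_q: float,
) -> float:
    """(target Ezh2/IgG ratio) / (Hprt Ezh2/IgG ratio); 1 = Hprt-like, <1 depleted."""
    _check_positive(
        ezh2_chip_q=ezh2_chip_q, igg_chip_q=igg_chip_q,
        hprt_ezh2_q=hprt_ezh2_q, hprt_igg_q=hprt_igg_q,
    )
    return (ezh2_chip_q / igg_chip_q) / (hprt_ezh2_q / hprt_igg_q)


def relative_transcript(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Fold change = 2^(-ddCt) with ddCt = dCt(sample) - dCt(calibrator)."""
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return float(2.0 ** (-ddct))
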