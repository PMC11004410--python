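"""Pull-down band-ratio quantification.

Each lane's captured-APOA1 band is normalized by the immobilized
SR-B1-GFP band and by the APOA1 input band; the variant's normalized
capture is then expressed relative to wild type.
"""

from transcyt import PulldownLane, pulldown_binding_ratio

lanes = [
    PulldownLane("WT", bound=12.0, srb1=3.0, input=5.0),
    PulldownLane("Milano", bound=27.0, srb1=3.1, input=5.2),
]
ratio = pulldown_binding_ratio(lanes)
print(f"Milano / WT normalized capture: {ratio:.2f}")
# A ratio above 1 means more APOA1-Milano than wild type was captured per
# unit of immobilized receptor and input protein.
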