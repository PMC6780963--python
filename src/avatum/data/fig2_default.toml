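# Default microchannel + trap geometry. Dimensions in micrometres.
#
# APPROXIMATE: the published U-shaped-barrier / microwell spheroid
# traps this design follows (the Barisam et al. perfusion
# microbioreactors) state their dimensions only on a figure; the values
# below are a plausible reconstruction at the same scale — a
# millimetre-scale channel with a trap sized for spheroids growing to a
# few hundred micrometres — and every one of them can be overridden.
# The two trap variants share length, width (hence cross-section area)
# and height by construction.

[channel]
length_um = 3000.0
width_um = 1200.0
height_um = 800.0

[trap]
length_um = 700.0   # along the flow axis
width_um = 700.0    # across the channel
height_um = 250.0   # barrier height / well depth
wall_um = 50.0      # U-barrier wall thickness (ignored by the microwell)
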