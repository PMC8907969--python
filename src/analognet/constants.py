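"""Topology and resolution constants of the emulated analog core.

The numbers describe one full-sized core: four quadrants of a 256x128
synaptic crossbar feeding 512 neuron circuits, with 6-bit synaptic weights
and source addresses, an 8-bit columnar ADC (CADC) for row-parallel
readout, and 24 analog bias parameters per neuron provided by a 10-bit DAC.
Dynamics run in the accelerated "hardware" time domain, nominally 1000x
faster than biological time.
"""

N_QUADRANTS = 4
ROWS_PER_QUADRANT = 256
COLS_PER_QUADRANT = 128
N_NEURONS = N_QUADRANTS * COLS_PER_QUADRANT          # 512
N_SYNAPSES = N_QUADRANTS * ROWS_PER_QUADRANT * COLS_PER_QUADRANT  # 2**17

WEIGHT_BITS = 6
WEIGHT_MAX = 2**WEIGHT_BITS - 1                      # 63
ADDRESS_BITS = 6
ADDRESS_MAX = 2**ADDRESS_BITS - 1                    # 63
PAYLOAD_BITS = 5
PAYLOAD_MAX = 2**PAYLOAD_BITS - 1                    # 31 = full unit pulse

CADC_BITS = 8
CADC_LEVELS = 2**CADC_BITS                           # 256
CADC_CHANNELS_PER_QUADRANT = 256                     # pairwise causal/acausal
CADC_SAMPLING_PERIOD = 1.7e-6                        # s, hardware time

DAC_BITS = 10
DAC_CODE_MAX = 2**DAC_BITS - 1                       # 1023
N_ANALOG_PARAMETERS = 24

ACCELERATION_FACTOR = 1000.0                         # hardware vs biological time

DEFAULT_DT = 1e-7                                    # s, 0.1 us integration step
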