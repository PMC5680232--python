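"""Internal unit system.

All force-field and dynamics arithmetic runs in a micrometre / nanogram /
microsecond system chosen so that the numbers of this problem sit near unity:

================  ==============  =======================
quantity          internal unit   SI equivalent
================  ==============  =======================
length            um              1e-6 m
mass              ng              1e-12 kg
time              us              1e-6 s
velocity          um/us           1 m/s
force             uN              1e-6 N
energy            pJ              1e-12 J
stress            MPa             1e6 Pa
spring constant   uN/um           1 N/m
================  ==============  =======================

Public constructors accept SI values (as printed in the source literature);
conversions are centralized here and round-trip tested.
"""

# length
M_TO_UM = 1e6
UM_TO_M = 1e-6
MM_TO_UM = 1e3

# mass
G_TO_NG = 1e9
KG_TO_NG = 1e12

# time
S_TO_US = 1e6
US_TO_S = 1e-6

# energy
J_TO_PJ = 1e12
PJ_TO_J = 1e-12

# force
N_TO_UN = 1e6
UN_TO_N = 1e-6

# stress (internal uN/um^2 = 1e6 Pa = 1 MPa)
PA_TO_MPA = 1e-6
MPA_TO_PA = 1e6
GPA_TO_MPA = 1e3
MPA_TO_GPA = 1e-3

# inverse length
PER_M_TO_PER_UM = 1e-6

# strain rate
PER_S_TO_PER_US = 1e-6

# toughness: internal MPa * strain == MJ/m^3 exactly (1e6 J/m^3)
MPA_TO_MJ_PER_M3 = 1.0
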