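# ICD-10 code registry for road traffic mortality quality assessment.
#
# Five categories of nonspecific ("garbage") cause-of-death codes sit at
# nested levels of the cause hierarchy:
#   all causes > injuries > unintentional injuries > transport > road traffic.
# Each category owns (a) a garbage code set, (b) the denominator against
# which its share is measured (its hierarchy level, garbage included), and
# (c) the target set its deaths are redistributed into (specific codes only;
# any code in any garbage set is excluded from every target at load time).
#
# Ranges "V01-V09" are inclusive at the 3-character level; "V87.0-V87.8"
# enumerates 4th-character children of one stem.
version: 1
garbage_sets:
  ILL_DEFINED: [R95, R96, R98, R99]
  UNDETERMINED_INTENT: [Y34, Y87.2, Y89.9]
  UNSPEC_UNINTENTIONAL: [X59]
  UNSPEC_TRANSPORT: [V99, Y85.9]
  UNSPEC_RT: [V87.0-V87.8, V89.2]
denominators:
  ILL_DEFINED: [A00-Z99]        # all causes
  UNDETERMINED_INTENT: [V01-Y89]  # all injury deaths
  UNSPEC_UNINTENTIONAL: [V01-X59] # unintentional injury deaths
  UNSPEC_TRANSPORT: [V01-V99, Y85] # transport crash deaths incl. their sequelae
  UNSPEC_RT: [V01-V89]            # road traffic deaths
targets:
  ILL_DEFINED: [A00-Z99]          # all specific causes
  UNDETERMINED_INTENT: [V01-Y89]  # specific injury causes
  UNSPEC_UNINTENTIONAL: [V01-X59] # specific unintentional injury causes
  UNSPEC_TRANSPORT: [V01-V98]     # specific transport causes (V99 itself is garbage)
  UNSPEC_RT: [V20-V79]            # occupants and motorcyclists only
road_user_groups:
  PEDESTRIAN: [V01-V09]
  PEDAL_CYCLIST: [V10-V19]
  MOTORCYCLIST: [V20-V29]
  OCCUPANT: [V30-V79]
  OTHER_RT: [V80-V89]             # incl. specific residuals V87.9, V89.0/.1/.3/.9
road_traffic: [V01-V89]
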