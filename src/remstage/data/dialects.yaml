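# Hypnogram dialect tables.
#
# Each dialect gives the native scoring-epoch length in seconds and a
# token -> stage mapping onto the AASM vocabulary (AWA, REM, N1, N2, N3,
# UNSCORED).  Native epochs shorter than 30 s are aggregated to the 30-s
# grid by majority vote with ties mapped to UNSCORED.
#
# Only "simple" (one token per line, plain CSV) is normative for this
# package; the "dreams" and "cap" tables below are sensible defaults for
# archive-style files and are meant to be edited by the user to match the
# actual export of their scoring software.

simple:
  epoch_length_s: 30
  mapping:
    "W": AWA
    "AWA": AWA
    "R": REM
    "REM": REM
    "1": N1
    "N1": N1
    "2": N2
    "N2": N2
    "3": N3
    "N3": N3
    "0": UNSCORED
    "-1": UNSCORED
    "-2": UNSCORED
    "U": UNSCORED
    "UNSCORED": UNSCORED
  write:
    AWA: "W"
    REM: "R"
    N1: "1"
    N2: "2"
    N3: "3"
    UNSCORED: "0"

dreams:
  # Numeric AASM export, one code per 5-s scoring epoch.
  epoch_length_s: 5
  mapping:
    "5": AWA
    "4": REM
    "3": N1
    "2": N2
    "1": N3
    "0": UNSCORED
    "-1": UNSCORED
    "-2": UNSCORED
  write:
    AWA: "5"
    REM: "4"
    N1: "3"
    N2: "2"
    N3: "1"
    UNSCORED: "0"

cap:
  # R&K-style text labels, one per 30-s epoch; S3/S4 collapse onto N3.
  epoch_length_s: 30
  mapping:
    "W": AWA
    "R": REM
    "REM": REM
    "S1": N1
    "S2": N2
    "S3": N3
    "S4": N3
    "MT": UNSCORED
    "?": UNSCORED
    "0": UNSCORED
    "-1": UNSCORED
    "-2": UNSCORED
  write:
    AWA: "W"
    REM: "R"
    N1: "S1"
    N2: "S2"
    N3: "S3"
    UNSCORED: "?"
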