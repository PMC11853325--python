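# Frequency-multiplier (FM) table of the revised NIOSH lifting equation,
# transcribed from the NIOSH Applications Manual (Waters et al.).
# Columns: one list per (work duration, vertical band) pair.
#   v_low  : vertical hand location V < 30 in (75 cm)
#   v_high : V >= 30 in (75 cm)
# Rows follow `frequencies` (lifts/min); lifting more often than 15/min
# gets FM = 0, less often than 0.2/min uses the 0.2 row.
version: "1994-applications-manual"
frequencies: [0.2, 0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]
le1h:
  v_low:  [1.00, 0.97, 0.94, 0.91, 0.88, 0.84, 0.80, 0.75, 0.70, 0.60, 0.52, 0.45, 0.41, 0.37, 0.00, 0.00, 0.00]
  v_high: [1.00, 0.97, 0.94, 0.91, 0.88, 0.84, 0.80, 0.75, 0.70, 0.60, 0.52, 0.45, 0.41, 0.37, 0.34, 0.31, 0.28]
le2h:
  v_low:  [0.95, 0.92, 0.88, 0.84, 0.79, 0.72, 0.60, 0.50, 0.42, 0.35, 0.30, 0.26, 0.00, 0.00, 0.00, 0.00, 0.00]
  v_high: [0.95, 0.92, 0.88, 0.84, 0.79, 0.72, 0.60, 0.50, 0.42, 0.35, 0.30, 0.26, 0.23, 0.21, 0.00, 0.00, 0.00]
le8h:
  v_low:  [0.85, 0.81, 0.75, 0.65, 0.55, 0.45, 0.35, 0.27, 0.22, 0.18, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00]
  v_high: [0.85, 0.81, 0.75, 0.65, 0.55, 0.45, 0.35, 0.27, 0.22, 0.18, 0.15, 0.13, 0.00, 0.00, 0.00, 0.00, 0.00]
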