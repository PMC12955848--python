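# Nearest-neighbor free-energy parameters (kcal/mol, 37 C).
# Turner-2004-derived "lite" set: Watson-Crick/wobble stacking, loop-length
# initiation tables, affine multiloop penalty, terminal AU/GU helix-end
# penalty.  No dangling ends, no mismatch/bonus terms, no loop asymmetry.
#
# stack P Q v : symmetric-table entry.  The physical energy of outer pair
# (a,b) stacked on inner pair (c,d) is looked up as stack[pair(a,b)][pair(d,c)]
# (the inner pair is read 3'->5'), which makes the table symmetric.
stack CG CG -2.40
stack CG GC -3.30
stack CG GU -2.10
stack CG UG -1.40
stack CG AU -2.10
stack CG UA -2.10
stack GC GC -3.40
stack GC GU -2.50
stack GC UG -1.50
stack GC AU -2.20
stack GC UA -2.40
stack GU GU 1.30
stack GU UG -0.50
stack GU AU -1.40
stack GU UA -1.30
stack UG UG 0.30
stack UG AU -0.60
stack UG UA -1.00
stack AU AU -1.10
stack AU UA -0.90
stack UA UA -1.30
# hairpin-loop initiation by loop length (unpaired nucleotides)
hairpin 3 5.40
hairpin 4 5.60
hairpin 5 5.70
hairpin 6 5.40
hairpin 7 6.00
hairpin 8 5.50
hairpin 9 6.40
hairpin 10 6.50
hairpin 11 6.60
hairpin 12 6.70
hairpin 13 6.78
hairpin 14 6.86
hairpin 15 6.94
hairpin 16 7.01
hairpin 17 7.07
hairpin 18 7.13
hairpin 19 7.19
hairpin 20 7.25
hairpin 21 7.30
hairpin 22 7.35
hairpin 23 7.40
hairpin 24 7.44
hairpin 25 7.49
hairpin 26 7.53
hairpin 27 7.57
hairpin 28 7.61
hairpin 29 7.65
hairpin 30 7.69
# bulge-loop initiation by total bulged nucleotides
bulge 1 3.80
bulge 2 2.80
bulge 3 3.20
bulge 4 3.60
bulge 5 4.00
bulge 6 4.40
bulge 7 4.59
bulge 8 4.70
bulge 9 4.80
bulge 10 4.90
bulge 11 5.00
bulge 12 5.10
bulge 13 5.19
bulge 14 5.27
bulge 15 5.34
bulge 16 5.41
bulge 17 5.48
bulge 18 5.54
bulge 19 5.60
bulge 20 5.65
bulge 21 5.71
bulge 22 5.76
bulge 23 5.80
bulge 24 5.85
bulge 25 5.89
bulge 26 5.94
bulge 27 5.98
bulge 28 6.02
bulge 29 6.05
bulge 30 6.09
# internal-loop initiation by total unpaired nucleotides (both sides);
# sizes 2 and 3 reuse the size-4 initiation (1x1 / 1x2 special tables are
# outside this parameter surface)
internal 2 1.10
internal 3 1.10
internal 4 1.10
internal 5 2.00
internal 6 2.00
internal 7 2.10
internal 8 2.30
internal 9 2.40
internal 10 2.50
internal 11 2.60
internal 12 2.70
internal 13 2.78
internal 14 2.86
internal 15 2.94
internal 16 3.01
internal 17 3.07
internal 18 3.13
internal 19 3.19
internal 20 3.25
internal 21 3.30
internal 22 3.35
internal 23 3.40
internal 24 3.44
internal 25 3.49
internal 26 3.53
internal 27 3.57
internal 28 3.61
internal 29 3.65
internal 30 3.69
# affine multiloop model: closing penalty a, per-branch b (closing pair
# included), per-unpaired c
multiloop a 9.30
multiloop b -0.90
multiloop c 0.00
# helix-end penalty for AU/UA/GU/UG pairs adjacent to any non-stack loop
terminal_au 0.50
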