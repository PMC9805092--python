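# Synthetic stand-in reference table for the para-nitrophenol molar
# extinction coefficient at ~405 nm as a function of pH, generated from the
# Henderson-Hasselbalch ionization model epsilon(pH) = epsilon_max /
# (1 + 10^(pKa - pH)) with literature values pKa = 7.15 and epsilon_max =
# 18000 1/(M cm) (Biggs, 1954, characterized this curve experimentally; the
# original tabulated values are not redistributed here).
pH,epsilon_M_cm
6.0,1190.1
6.5,3292.6
7.0,7461.0
7.15,9000.0
7.5,12442.3
8.0,15772.1
8.5,17230.3
9.0,17749.3
9.5,17920.0
10.0,17974.6
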