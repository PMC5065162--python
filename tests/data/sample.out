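   SW  perc perc perc  query      position in query           matching       repeat              position in  repeat
score  div. del. ins.  sequence    begin     end    (left)    repeat         class/family         begin  end (left)   ID

  463 28.6 0.0 0.0 chr1 101 200 (149800) + AmnSINE1 SINE/Deu 391 501 (49) 1
  239 27.2 1.9 1.0 chr1 501 850 (149150) C MER117 DNA/hAT-Charlie (0) 350 1 2
 2000 25.6 0.0 0.0 chr1 1001 1400 (148600) + X6b_DNA DNA 1 400 (0) 3
  180 12.0 0.0 0.0 chr1 2001 2110 (147890) + MIR SINE/MIR 40 149 (110) 4
   95 5.0 0.0 0.0 chr1 3001 3050 (146950) + (TA)n Simple_repeat 1 50 (0) 5
   88 4.0 0.0 0.0 chr1 3200 3260 (146740) + A-rich Low_complexity 1 60 (0) 6
  700 18.5 2.0 0.5 chr2 5001 5420 (94580) C L1MC5a LINE/L1 (1500) 4500 4090 7
  310 22.0 0.0 1.0 chr2 7001 7180 (92820) + MER117 DNA/hAT-Charlie 120 299 (51) 8
  150 30.0 0.0 0.0 chr2 7300 7390 (92610) + AmnSINE1 SINE/Deu 391 481 (69) 8
  420 15.0 0.0 0.0 chr2 9001 9200 (90800) C MLT1K LTR/ERVL-MaLR (0) 500 301 9 *
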