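rosiglitazone (synthetic ETKDG pose, not the crystal pose)
     RDKit          3D

 25 27  0  0  0  0  0  0  0  0999 V2000
    3.4239   -2.2441   -1.4009 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.6849   -0.8320   -1.1647 N   0  0  0  0  0  0  0  0  0  0  0  0
    2.6613    0.1219   -1.6216 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.4315    0.1811   -0.7051 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.3944    0.8976   -1.3856 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.7972    1.0376   -0.7303 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.7911    1.6922   -1.4596 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.0587    1.9027   -0.9119 C   0  0  0  0  0  0  0  0  0  0  0  0
   -3.3543    1.4555    0.3804 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.7302    1.6615    0.9747 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.7274    0.5150    0.7757 C   0  0  0  0  0  0  0  0  0  0  0  0
   -6.1391    0.1632   -0.9682 S   0  0  0  0  0  0  0  0  0  0  0  0
   -5.6060   -1.4940   -0.8596 C   0  0  0  0  0  0  0  0  0  0  0  0
   -5.6315   -2.2795   -1.7913 O   0  0  0  0  0  0  0  0  0  0  0  0
   -5.1889   -1.7782    0.3956 N   0  0  0  0  0  0  0  0  0  0  0  0
   -5.2237   -0.7965    1.3384 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.8936   -0.9745    2.5044 O   0  0  0  0  0  0  0  0  0  0  0  0
   -2.3508    0.8076    1.1132 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0816    0.5988    0.5616 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.4569   -0.4483   -0.0710 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.4131   -1.2955    0.4940 C   0  0  0  0  0  0  0  0  0  0  0  0
    6.1803   -0.8728    1.5818 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.9901    0.3994    2.0918 C   0  0  0  0  0  0  0  0  0  0  0  0
    5.0394    1.1921    1.4836 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.2869    0.7955    0.4322 N   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  4  5  1  0
  5  6  1  0
  6  7  2  0
  7  8  1  0
  8  9  2  0
  9 10  1  0
 10 11  1  0
 11 12  1  0
 12 13  1  0
 13 14  2  0
 13 15  1  0
 15 16  1  0
 16 17  2  0
  9 18  1  0
 18 19  2  0
  2 20  1  0
 20 21  2  0
 21 22  1  0
 22 23  2  0
 23 24  1  0
 24 25  2  0
 19  6  1  0
 25 20  1  0
 16 11  1  0
M  END
$$$$
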