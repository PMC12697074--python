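P1 = (209.57, −7.127), P2 = (87.129, −82.243), P3 = (304.57, −116.127), P4 = (466.57, −127.127), P5 = (189.57, −157.127), P6 = (117.57, −194.127), P7 = (347.57, −206.127), P8 = (388.57, −235.127), P9 = (569.57, −236.127), P10 = (244.57, −253.127), P11 = (658.57, −259.127), P12 = (54.57, −264.127), P13 = (513.129, −284.243), P14 = (126.57, −302.127), P15 = (353.57, −331.127), P16 = (214.57, −347.127), P17 = (558.57, −354.127), P18 = (471.57, −379.127), P19 = (7.548, −410.596), P20 = (378.129, −434.243), P21 = (133.57, −443.127), P22 = (272.57, −456.127)
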