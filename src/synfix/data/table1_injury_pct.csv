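# Transcription of the published 90-cell peroneal-artery injury-potential table:
# per (placement level above the joint, trajectory rule, shaft diameter) the
# percentage of the 100 CT-angiography ankles flagged (distance <= radius).
# Percentages are integers because each cell counts flags over n = 100 ankles.
level_cm,angle_rule,diameter_mm,pct
0.5,fixed_20,3.5,0
0.5,fixed_20,4.0,0
0.5,fixed_20,4.5,0
0.5,fixed_30,3.5,0
0.5,fixed_30,4.0,0
0.5,fixed_30,4.5,0
0.5,individual,3.5,0
0.5,individual,4.0,0
0.5,individual,4.5,0
1.0,fixed_20,3.5,0
1.0,fixed_20,4.0,0
1.0,fixed_20,4.5,0
1.0,fixed_30,3.5,0
1.0,fixed_30,4.0,0
1.0,fixed_30,4.5,0
1.0,individual,3.5,0
1.0,individual,4.0,0
1.0,individual,4.5,0
1.5,fixed_20,3.5,7
1.5,fixed_20,4.0,8
1.5,fixed_20,4.5,10
1.5,fixed_30,3.5,4
1.5,fixed_30,4.0,4
1.5,fixed_30,4.5,4
1.5,individual,3.5,1
1.5,individual,4.0,2
1.5,individual,4.5,2
2.0,fixed_20,3.5,32
2.0,fixed_20,4.0,33
2.0,fixed_20,4.5,36
2.0,fixed_30,3.5,17
2.0,fixed_30,4.0,22
2.0,fixed_30,4.5,24
2.0,individual,3.5,14
2.0,individual,4.0,14
2.0,individual,4.5,15
2.5,fixed_20,3.5,42
2.5,fixed_20,4.0,43
2.5,fixed_20,4.5,47
2.5,fixed_30,3.5,37
2.5,fixed_30,4.0,41
2.5,fixed_30,4.5,44
2.5,individual,3.5,36
2.5,individual,4.0,41
2.5,individual,4.5,45
3.0,fixed_20,3.5,42
3.0,fixed_20,4.0,51
3.0,fixed_20,4.5,51
3.0,fixed_30,3.5,51
3.0,fixed_30,4.0,62
3.0,fixed_30,4.5,65
3.0,individual,3.5,70
3.0,individual,4.0,73
3.0,individual,4.5,76
3.5,fixed_20,3.5,45
3.5,fixed_20,4.0,51
3.5,fixed_20,4.5,54
3.5,fixed_30,3.5,60
3.5,fixed_30,4.0,65
3.5,fixed_30,4.5,67
3.5,individual,3.5,80
3.5,individual,4.0,81
3.5,individual,4.5,84
4.0,fixed_20,3.5,40
4.0,fixed_20,4.0,47
4.0,fixed_20,4.5,51
4.0,fixed_30,3.5,61
4.0,fixed_30,4.0,62
4.0,fixed_30,4.5,66
4.0,individual,3.5,82
4.0,individual,4.0,85
4.0,individual,4.5,86
4.5,fixed_20,3.5,39
4.5,fixed_20,4.0,46
4.5,fixed_20,4.5,50
4.5,fixed_30,3.5,57
4.5,fixed_30,4.0,62
4.5,fixed_30,4.5,64
4.5,individual,3.5,87
4.5,individual,4.0,87
4.5,individual,4.5,89
5.0,fixed_20,3.5,43
5.0,fixed_20,4.0,47
5.0,fixed_20,4.5,54
5.0,fixed_30,3.5,59
5.0,fixed_30,4.0,60
5.0,fixed_30,4.5,65
5.0,individual,3.5,85
5.0,individual,4.0,87
5.0,individual,4.5,87
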