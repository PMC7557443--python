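group,sample,area,method,width_um
1,1,vestibular,microscopy,31
1,1,vestibular,microct,20
1,1,oral,microscopy,230
1,1,oral,microct,210
1,1,pulpal,microscopy,290
1,1,pulpal,microct,180
1,2,vestibular,microscopy,90
1,2,vestibular,microct,90
1,2,oral,microscopy,47
1,2,oral,microct,71
1,2,pulpal,microscopy,170
1,2,pulpal,microct,100
1,3,vestibular,microscopy,240
1,3,vestibular,microct,31
1,3,oral,microscopy,210
1,3,oral,microct,47
1,3,pulpal,microscopy,90
1,3,pulpal,microct,170
1,4,vestibular,microscopy,21
1,4,vestibular,microct,400
1,4,oral,microscopy,63
1,4,oral,microct,220
1,4,pulpal,microscopy,60
1,4,pulpal,microct,91
1,5,vestibular,microscopy,50
1,5,vestibular,microct,72
1,5,oral,microscopy,37
1,5,oral,microct,61
1,5,pulpal,microscopy,59
1,5,pulpal,microct,20
2,1,vestibular,microscopy,21
2,1,vestibular,microct,17
2,1,oral,microscopy,71
2,1,oral,microct,21
2,1,pulpal,microscopy,42
2,1,pulpal,microct,92
2,2,vestibular,microscopy,120
2,2,vestibular,microct,110
2,2,oral,microscopy,170
2,2,oral,microct,73
2,2,pulpal,microscopy,30
2,2,pulpal,microct,64
2,3,vestibular,microscopy,53
2,3,vestibular,microct,400
2,3,oral,microscopy,160
2,3,oral,microct,56
2,3,pulpal,microscopy,16
2,3,pulpal,microct,270
2,4,vestibular,microscopy,67
2,4,vestibular,microct,29
2,4,oral,microscopy,31
2,4,oral,microct,46
2,4,pulpal,microscopy,70
2,4,pulpal,microct,23
2,5,vestibular,microscopy,59
2,5,vestibular,microct,190
2,5,oral,microscopy,130
2,5,oral,microct,210
2,5,pulpal,microscopy,310
2,5,pulpal,microct,77
3,1,vestibular,microscopy,37
3,1,vestibular,microct,13
3,1,oral,microscopy,47
3,1,oral,microct,19
3,1,pulpal,microscopy,41
3,1,pulpal,microct,22
3,2,vestibular,microscopy,50
3,2,vestibular,microct,18
3,2,oral,microscopy,22
3,2,oral,microct,24
3,2,pulpal,microscopy,90
3,2,pulpal,microct,98
3,3,vestibular,microscopy,29
3,3,vestibular,microct,32
3,3,oral,microscopy,30
3,3,oral,microct,38
3,3,pulpal,microscopy,54
3,3,pulpal,microct,29
3,4,vestibular,microscopy,180
3,4,vestibular,microct,88
3,4,oral,microscopy,40
3,4,oral,microct,91
3,4,pulpal,microscopy,61
3,4,pulpal,microct,100
3,5,vestibular,microscopy,13
3,5,vestibular,microct,36
3,5,oral,microscopy,190
3,5,oral,microct,66
3,5,pulpal,microscopy,170
3,5,pulpal,microct,310
4,1,vestibular,microscopy,29
4,1,vestibular,microct,17
4,1,oral,microscopy,40
4,1,oral,microct,23
4,1,pulpal,microscopy,31
4,1,pulpal,microct,20
4,2,vestibular,microscopy,21
4,2,vestibular,microct,21
4,2,oral,microscopy,12
4,2,oral,microct,16
4,2,pulpal,microscopy,33
4,2,pulpal,microct,32
4,3,vestibular,microscopy,31
4,3,vestibular,microct,30
4,3,oral,microscopy,37
4,3,oral,microct,21
4,3,pulpal,microscopy,17
4,3,pulpal,microct,11
4,4,vestibular,microscopy,11
4,4,vestibular,microct,21
4,4,oral,microscopy,39
4,4,oral,microct,11
4,4,pulpal,microscopy,21
4,4,pulpal,microct,15
4,5,vestibular,microscopy,37
4,5,vestibular,microct,14
4,5,oral,microscopy,29
4,5,oral,microct,24
4,5,pulpal,microscopy,22
4,5,pulpal,microct,27
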