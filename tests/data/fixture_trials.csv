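subject,session,block,trial,set_size,rss_list,rss_new,is_recall,analyze,response_category,probed_position,response_word
1,1,1,29,6,6,0,False,True,other_list,4,w0724
1,1,1,30,6,4,0,False,True,other_list,6,w0017
1,1,1,31,6,4,4,False,True,correct,6,w0725
1,1,1,32,4,4,0,False,True,correct,2,w0377
1,1,1,33,2,0,0,True,True,correct,1,w0415
1,1,1,34,8,6,0,False,True,other_list,2,w0964
1,1,1,35,6,2,0,False,True,correct,4,w0179
1,1,1,36,8,8,4,False,True,correct,4,w0828
1,1,1,37,4,4,4,False,True,other_list,4,w0047
1,1,1,38,2,1,1,False,True,correct,2,w1096
1,1,1,39,4,0,0,True,True,correct,4,w0288
1,1,1,40,4,2,0,False,True,correct,4,w0743
1,1,1,41,8,2,2,False,True,correct,1,w1163
1,1,1,42,8,4,0,False,True,correct,5,w0612
1,1,1,43,4,1,1,False,True,correct,1,w0378
1,1,1,44,8,0,0,True,True,correct,6,w0078
1,1,1,45,6,2,2,False,True,correct,3,w0915
1,1,1,46,8,1,1,False,True,correct,8,w0195
1,1,1,47,6,0,0,True,True,correct,4,w0854
1,1,1,48,6,1,1,False,True,correct,6,w0212
1,1,1,49,6,6,4,False,True,correct,6,w0837
1,1,1,50,2,2,2,False,True,correct,1,w0166
1,1,1,51,8,2,0,False,True,correct,4,w1197
1,1,1,52,8,4,4,False,True,correct,5,w0742
1,1,1,53,2,2,0,False,True,correct,2,w0977
1,1,1,54,8,6,4,False,True,correct,2,w0147
1,1,1,55,8,8,0,False,True,correct,8,w0789
1,1,1,56,4,2,2,False,True,correct,3,w1170
2,1,1,29,6,6,0,False,True,other_list,3,w0526
2,1,1,30,6,4,0,False,True,correct,4,w0689
2,1,1,31,6,4,4,False,True,correct,1,w0475
2,1,1,32,4,4,0,False,True,correct,4,w0382
2,1,1,33,2,0,0,True,True,correct,2,w0527
2,1,1,34,8,6,0,False,True,correct,4,w1167
2,1,1,35,6,2,0,False,True,correct,4,w1138
2,1,1,36,8,8,4,False,True,correct,3,w0861
2,1,1,37,4,4,4,False,True,correct,2,w0901
2,1,1,38,2,1,1,False,True,correct,2,w0743
2,1,1,39,4,0,0,True,True,correct,4,w0372
2,1,1,40,4,2,0,False,True,correct,1,w0655
2,1,1,41,8,2,2,False,True,correct,7,w0077
2,1,1,42,8,4,0,False,True,correct,3,w0013
2,1,1,43,4,1,1,False,True,correct,1,w0308
2,1,1,44,8,0,0,True,True,correct,5,w0040
2,1,1,45,6,2,2,False,True,correct,2,w1117
2,1,1,46,8,1,1,False,True,correct,7,w0448
2,1,1,47,6,0,0,True,True,other_list,4,w0407
2,1,1,48,6,1,1,False,True,correct,4,w0302
2,1,1,49,6,6,4,False,True,correct,4,w0973
2,1,1,50,2,2,2,False,True,correct,1,w0162
2,1,1,51,8,2,0,False,True,correct,1,w0272
2,1,1,52,8,4,4,False,True,correct,2,w1055
2,1,1,53,2,2,0,False,True,correct,2,w1141
2,1,1,54,8,6,4,False,True,other_list,2,w0434
2,1,1,55,8,8,0,False,True,correct,3,w0750
2,1,1,56,4,2,2,False,True,correct,1,w1130
3,1,1,29,6,6,0,False,True,other_list,6,w1118
3,1,1,30,6,4,0,False,True,correct,2,w0855
3,1,1,31,6,4,4,False,True,correct,2,w1000
3,1,1,32,4,4,0,False,True,correct,1,w1048
3,1,1,33,2,0,0,True,True,correct,2,w0212
3,1,1,34,8,6,0,False,True,other_list,7,w0020
3,1,1,35,6,2,0,False,True,correct,2,w0714
3,1,1,36,8,8,4,False,True,other_list,2,w0031
3,1,1,37,4,4,4,False,True,correct,4,w1049
3,1,1,38,2,1,1,False,True,correct,1,w0662
3,1,1,39,4,0,0,True,True,other_list,4,w0445
3,1,1,40,4,2,0,False,True,other_list,4,w1172
3,1,1,41,8,2,2,False,True,other_list,3,w0475
3,1,1,42,8,4,0,False,True,other_list,4,w0246
3,1,1,43,4,1,1,False,True,correct,2,w0762
3,1,1,44,8,0,0,True,True,other_list,8,w0792
3,1,1,45,6,2,2,False,True,correct,5,w0053
3,1,1,46,8,1,1,False,True,correct,8,w0202
3,1,1,47,6,0,0,True,True,other_list,3,w0691
3,1,1,48,6,1,1,False,True,correct,1,w0423
3,1,1,49,6,6,4,False,True,other_list,3,w0358
3,1,1,50,2,2,2,False,True,correct,2,w0614
3,1,1,51,8,2,0,False,True,correct,7,w0319
3,1,1,52,8,4,4,False,True,other_list,6,w0983
3,1,1,53,2,2,0,False,True,correct,1,w1011
3,1,1,54,8,6,4,False,True,other_list,1,w0382
3,1,1,55,8,8,0,False,True,other_list,6,w1126
3,1,1,56,4,2,2,False,True,correct,4,w1023
4,1,1,29,6,6,0,False,True,correct,3,w0968
4,1,1,30,6,4,0,False,True,correct,6,w0342
4,1,1,31,6,4,4,False,True,correct,5,w0627
4,1,1,32,4,4,0,False,True,correct,1,w0254
4,1,1,33,2,0,0,True,True,correct,1,w1143
4,1,1,34,8,6,0,False,True,correct,6,w0097
4,1,1,35,6,2,0,False,True,correct,2,w0266
4,1,1,36,8,8,4,False,True,other_list,7,w0217
4,1,1,37,4,4,4,False,True,new,3,w0717
4,1,1,38,2,1,1,False,True,new,2,w1153
4,1,1,39,4,0,0,True,True,correct,3,w0101
4,1,1,40,4,2,0,False,True,correct,4,w1177
4,1,1,41,8,2,2,False,True,other_list,5,w0343
4,1,1,42,8,4,0,False,True,correct,2,w0609
4,1,1,43,4,1,1,False,True,correct,1,w0964
4,1,1,44,8,0,0,True,True,other_list,3,w0753
4,1,1,45,6,2,2,False,True,correct,3,w1081
4,1,1,46,8,1,1,False,True,correct,1,w0582
4,1,1,47,6,0,0,True,True,correct,1,w0901
4,1,1,48,6,1,1,False,True,correct,4,w0225
4,1,1,49,6,6,4,False,True,correct,4,w1186
4,1,1,50,2,2,2,False,True,correct,2,w0593
4,1,1,51,8,2,0,False,True,correct,8,w0491
4,1,1,52,8,4,4,False,True,correct,1,w1071
4,1,1,53,2,2,0,False,True,correct,1,w0974
4,1,1,54,8,6,4,False,True,other_list,6,w0250
4,1,1,55,8,8,0,False,True,correct,7,w0184
4,1,1,56,4,2,2,False,True,correct,1,w0611
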