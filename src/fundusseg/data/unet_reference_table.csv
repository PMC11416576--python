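block,layer,input,kernel,filters,activation,output,params
Down-sampling 1,InputLayer,512*512*3,,,,512*512*3,0
Down-sampling 1,Conv2D,512*512*3,3*3,8,ReLU,512*512*8,224
Down-sampling 1,Dropout,512*512*8,,,,512*512*8,0
Down-sampling 1,Conv2D,512*512*8,3*3,8,ReLU,512*512*8,284
Down-sampling 2,MaxPooling2D,512*512*8,,,,256*256*8,0
Down-sampling 2,Conv2D,256*256*8,3*3,16,ReLU,256*256*16,1168
Down-sampling 2,Dropout,256*256*16,,,,256*256*16,0
Down-sampling 2,Conv2D,256*256*16,3*3,16,ReLU,256*256*16,2320
Down-sampling 3,MaxPooling2D,256*256*16,,,,128*128*16,0
Down-sampling 3,Conv2D,128*128*16,3*3,32,ReLU,128*128*32,4640
Down-sampling 3,Dropout,128*128*32,,,,128*128*32,0
Down-sampling 3,Conv2D,128*128*32,3*3,32,ReLU,128*128*32,9248
Down-sampling 4,MaxPooling2D,128*128*32,,,,64*64*32,0
Down-sampling 4,Conv2D,64*64*32,3*3,64,ReLU,64*64*64,18496
Down-sampling 4,Dropout,64*64*64,,,,64*64*64,0
Down-sampling 4,Conv2D,64*64*64,3*3,64,ReLU,64*64*64,36928
Centre Block,MaxPooling2D,64*64*64,,,,32*32*64,0
Centre Block,Conv2D,32*32*64,3*3,128,ReLU,32*32*128,73856
Centre Block,Dropout,32*32*128,,,,32*32*128,0
Centre Block,Conv2D,32*32*128,3*3,128,ReLU,32*32*128,147584
Centre Block,Conv2DTranspose,32*32*128,2*2,64,Linear,64*64*64,32832
Up-sampling 1,Concatenate,64*64*64,,,,64*64*128,0
Up-sampling 1,Conv2D,64*64*128,3*3,64,ReLU,64*64*64,73792
Up-sampling 1,Dropout,64*64*64,,,,64*64*64,0
Up-sampling 1,Conv2D,64*64*64,3*3,64,ReLU,64*64*64,36928
Up-sampling 1,Conv2DTranspose,64*64*64,2*2,32,Linear,128*128*32,8224
Up-sampling 2,Concatenate,128*128*32,,,,128*128*64,0
Up-sampling 2,Conv2D,128*128*64,3*3,32,ReLU,128*128*32,18464
Up-sampling 2,Dropout,128*128*32,,,,128*128*32,0
Up-sampling 2,Conv2D,128*128*32,3*3,32,ReLU,128*128*32,9248
Up-sampling 2,Conv2DTranspose,128*128*32,2*2,16,Linear,256*256*16,2064
Up-sampling 3,Concatenate,256*256*16,,,,256*256*32,0
Up-sampling 3,Conv2D,256*256*32,3*3,16,ReLU,256*256*16,4624
Up-sampling 3,Dropout,256*256*16,,,,256*256*16,0
Up-sampling 3,Conv2D,256*256*16,3*3,16,ReLU,256*256*16,2320
Up-sampling 3,Conv2DTranspose,256*256*16,2*2,8,Linear,512*512*8,520
Up-sampling 4,Concatenate,512*512*8,,,,512*512*16,0
Up-sampling 4,Conv2D,512*512*16,3*3,8,ReLU,512*512*8,1160
Up-sampling 4,Dropout,512*512*8,,,,512*512*8,0
Up-sampling 4,Conv2D,512*512*8,3*3,8,ReLU,512*512*8,584
Up-sampling 4,Conv2D,512*512*8,1*1,6,Softmax,512*512*6,54
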